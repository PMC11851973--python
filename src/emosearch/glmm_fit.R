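# Batch driver for the 2x2 generalized linear mixed models.
# Usage: Rscript glmm_fit.R jobs.json out.json
# Each job: {data: csv path, family: gamma|poisson|binomial,
#            link: inverse|log|logit, ref_emotion, ref_task}
# The model is always  y ~ emotion * task + (1 | participant).

suppressMessages({
  library(glmmTMB)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
jobs <- fromJSON(args[1], simplifyVector = FALSE)

fit_one <- function(job, link) {
  d <- read.csv(job$data)
  d$participant <- factor(d$participant)
  d$emotion <- relevel(factor(d$emotion), ref = job$ref_emotion)
  d$task <- relevel(factor(d$task), ref = job$ref_task)
  fam <- switch(job$family,
    gamma = Gamma(link = link),
    poisson = poisson(link = link),
    binomial = binomial(link = link))
  m <- glmmTMB(y ~ emotion * task + (1 | participant), data = d, family = fam)
  conv <- isTRUE(m$fit$convergence == 0) && isTRUE(m$sdr$pdHess)
  if (!conv) stop(sprintf("non-convergence (convergence=%s pdHess=%s)",
                          m$fit$convergence, m$sdr$pdHess))
  co <- summary(m)$coefficients$cond
  vc <- vcov(m)$cond
  list(
    ok = TRUE,
    link = link,
    coef_names = rownames(co),
    coef = as.numeric(co[, "Estimate"]),
    se = as.numeric(co[, "Std. Error"]),
    p = as.numeric(co[, ncol(co)]),
    vcov = lapply(seq_len(nrow(vc)), function(i) as.numeric(vc[i, ])),
    tau00 = as.numeric(VarCorr(m)$cond$participant[1, 1]),
    sigma = as.numeric(sigma(m)),
    n_obs = nrow(d),
    n_subjects = nlevels(d$participant),
    loglik = as.numeric(logLik(m))
  )
}

results <- lapply(jobs, function(job) {
  r <- try(fit_one(job, job$link), silent = TRUE)
  fallback <- FALSE
  if (inherits(r, "try-error") && job$link == "inverse") {
    # documented fallback for the numerically fragile gamma/inverse fit
    r2 <- try(fit_one(job, "log"), silent = TRUE)
    if (!inherits(r2, "try-error")) {
      r <- r2
      fallback <- TRUE
    }
  }
  if (inherits(r, "try-error")) {
    return(list(ok = FALSE, error = as.character(r)))
  }
  r$link_fallback <- fallback
  r
})

write_json(results, args[2], auto_unbox = TRUE, digits = 16)
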