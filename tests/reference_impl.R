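# Independent reference implementations of the group-comparison tests,
# used to cross-check the package: Welch's t, Mann-Whitney (asymptotic,
# continuity-corrected), Kruskal-Wallis, and Dunn's post hoc z-tests
# (Bonferroni-adjusted over the tested pairs).
#
# Usage: Rscript reference_impl.R input.json output.json
# input.json: a list of datasets, each a list of numeric group vectors.

suppressMessages(library(jsonlite))

dunn_adjusted_p <- function(groups) {
  x <- unlist(groups)
  grp <- rep(seq_along(groups), vapply(groups, length, 1L))
  r <- rank(x)
  N <- length(x)
  ties <- table(x)
  tie_term <- sum(ties^3 - ties) / (12 * (N - 1))
  v0 <- N * (N + 1) / 12 - tie_term
  mean_ranks <- tapply(r, grp, mean)
  n <- vapply(groups, length, 1L)
  k <- length(groups)
  m <- k * (k - 1) / 2
  out <- c()
  for (i in 1:(k - 1)) {
    for (j in (i + 1):k) {
      z <- (mean_ranks[i] - mean_ranks[j]) / sqrt(v0 * (1 / n[i] + 1 / n[j]))
      out <- c(out, min(1, 2 * pnorm(-abs(z)) * m))
    }
  }
  unname(out)
}

args <- commandArgs(trailingOnly = TRUE)
datasets <- fromJSON(args[1], simplifyVector = FALSE)

results <- lapply(datasets, function(d) {
  g <- lapply(d, as.numeric)
  list(
    welch_p = t.test(g[[1]], g[[2]], var.equal = FALSE)$p.value,
    mann_whitney_p = wilcox.test(g[[1]], g[[2]], exact = FALSE, correct = TRUE)$p.value,
    kruskal_p = kruskal.test(g)$p.value,
    dunn_p_adjusted = dunn_adjusted_p(g)
  )
})

write_json(results, args[2], digits = I(17), auto_unbox = TRUE)
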