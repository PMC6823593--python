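"""Alpha-diversity estimators and rarefaction, mothur conventions.

Estimators follow the conventions of the mothur summary.single calculators
so values are comparable with the field's standard amplicon summaries:

* observed richness  S_obs = #{i : n_i > 0}
* Good's coverage    C = 1 − n1/N        (n1 = singletons, N = reads)
* Chao1 richness     S_obs + n1(n1−1) / (2(n2+1))
* Shannon (plug-in)  H = −Σ p_i ln p_i   (natural log)
* non-parametric Shannon (Chao–Shen): coverage-adjusted frequencies
  p̃_i = Ĉ·p_i with Ĉ = 1 − n1/N, each term Horvitz–Thompson weighted by
  its detection probability 1 − (1−p̃_i)^N
* inverse Simpson    1 / [Σ n_i(n_i−1) / (N(N−1))]  (unbiased finite-sample
  form; the plug-in 1/Σp_i² is also available)
* Shannon evenness   H / ln S_obs

Undefined cases are reported as NaN, not errors: inverse Simpson when every
taxon is a singleton, evenness when S_obs = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = ["DiversitySummary", "alpha_summary", "alpha_table", "rarefy"]


@dataclass
class DiversitySummary:
    """Per-sample alpha diversity, in Table-style column order."""

    nseqs: int
    sobs: int
    coverage: float
    chao1: float
    np_shannon: float
    invsimpson: float
    evenness: float
    shannon: float  # plug-in estimator, supplementary

    def validate(self) -> None:
        assert self.chao1 >= self.sobs - 1e-9
        assert 0.0 <= self.coverage <= 1.0
        if self.sobs >= 2 and not math.isnan(self.evenness):
            assert -1e-9 <= self.evenness <= 1.0 + 1e-9
        if not math.isnan(self.invsimpson):
            assert self.invsimpson >= 1.0 - 1e-9


def alpha_summary(counts) -> DiversitySummary:
    """Compute the full alpha-diversity summary for one sample's counts."""
    n = np.asarray(counts)
    if n.size and not np.issubdtype(n.dtype, np.integer):
        if not np.allclose(n, np.round(n)):
            raise ValueError("counts must be integers")
        n = np.round(n).astype(np.int64)
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    n = n[n > 0]
    total = int(n.sum())
    if total == 0:
        raise ValueError("sample has zero reads")

    sobs = int(n.size)
    n1 = int((n == 1).sum())
    n2 = int((n == 2).sum())
    coverage = 1.0 - n1 / total
    chao1 = sobs + n1 * (n1 - 1) / (2.0 * (n2 + 1))

    p = n / total
    shannon = float(-(p * np.log(p)).sum())

    # Chao–Shen: coverage-adjust, then Horvitz–Thompson weight each term
    c_hat = coverage
    if c_hat > 0:
        cp = c_hat * p
        detect = 1.0 - (1.0 - cp) ** total
        np_shannon = float(-((cp * np.log(cp)) / detect).sum())
    else:
        np_shannon = float("nan")  # all reads are singletons

    d_sum = float((n * (n - 1)).sum())
    if d_sum > 0 and total > 1:
        invsimpson = total * (total - 1) / d_sum
    else:
        invsimpson = float("nan")
    evenness = shannon / math.log(sobs) if sobs >= 2 else float("nan")

    out = DiversitySummary(
        nseqs=total,
        sobs=sobs,
        coverage=coverage,
        chao1=chao1,
        np_shannon=np_shannon,
        invsimpson=invsimpson,
        evenness=evenness,
        shannon=shannon,
    )
    out.validate()
    return out


def plugin_invsimpson(counts) -> float:
    """Plug-in inverse Simpson 1/Σp_i² (supplementary convention)."""
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    p = n / n.sum()
    return float(1.0 / (p**2).sum())


def alpha_table(counts: CountMatrix) -> pd.DataFrame:
    """Alpha-diversity summary for every sample of a count matrix."""
    cols = [f.name for f in fields(DiversitySummary)]
    rows = {s: alpha_summary(counts.data[s].to_numpy()) for s in counts.samples}
    return pd.DataFrame(
        {s: [getattr(r, c) for c in cols] for s, r in rows.items()}, index=cols
    ).T.rename_axis("sample")


def rarefy(counts: CountMatrix, depth: int | None = None, seed: int = 0) -> CountMatrix:
    """Subsample each sample, without replacement, to a common depth.

    This is the "normalize to the lowest sequencing outcome" step: by
    default ``depth`` is the smallest per-sample total.  One draw is taken
    at the given seed (not an average over draws), matching mothur's
    sub.sample behaviour.
    """
    totals = counts.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("depth must be positive")
    shallow = totals.index[totals < depth]
    if len(shallow):
        raise ValueError(
            f"sample {shallow[0]!r} has only {totals[shallow[0]]} reads, below depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in counts.samples:
        col = counts.data[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    return CountMatrix(pd.DataFrame(out, index=counts.taxa), label=counts.label)
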