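"""Synthetic microbial communities with planted triplet interactions.

The generator emulates the statistical structure the rule model assumes: a
multi-sample relative-abundance matrix in which each planted target taxon's
abundance responds linearly to a cooperator (positively) and a competitor
(negatively), on top of a Dirichlet-like background, with optional Gaussian
noise.  Compositional closure (columns renormalized to sum 1) is deliberate
— real relative-abundance tables are compositional.

Per sample, background abundances are independent Gamma draws renormalized
to fractions.  Each planted target is then rewritten as

    raw_target = baseline + beta_coop · f_coop − beta_comp · f_comp + noise

where f_coop/f_comp are the regulators' background fractions, with the
default baseline set high enough that the competitive term cannot drive the
value negative (a 1e-6 floor remains as a safety net).  Regulator and target
rows are kept exactly; the remaining background rows are rescaled per sample
so columns sum to 1.  When the special rows alone exceed the sample total
(rare, extreme draws), the whole column is renormalized instead.

Samples are split half/half into two regions ("A" then "B") so region-aware
code paths can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix
from .network import COMPETITIVE, COOPERATIVE, InteractionNetwork

__all__ = ["SyntheticSpec", "generate_null", "generate_planted", "score_recovery"]


@dataclass
class SyntheticSpec:
    """Parameters of a planted-interaction community.

    planted holds (target, cooperator, competitor) taxon *indices*;
    beta_coop/beta_comp are response strengths (dimensionless multipliers on
    regulator fractions); noise_sd is the Gaussian noise on the target's raw
    abundance, in fraction units; baseline_concentration is the Gamma shape
    of the background (smaller = more uneven communities).
    """

    n_taxa: int = 8
    n_samples: int = 40
    planted: list[tuple[int, int, int]] = field(default_factory=list)
    beta_coop: float = 0.5
    beta_comp: float = 0.5
    noise_sd: float = 0.0
    baseline_concentration: float = 1.0
    target_baseline: float | None = None
    n_regions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        for trip in self.planted:
            if len(set(trip)) != 3:
                raise ValueError(f"planted triple has duplicate indices: {trip}")
            if any(not 0 <= i < self.n_taxa for i in trip):
                raise ValueError(f"planted index out of range: {trip}")


def _taxon_names(n: int) -> list[str]:
    return [f"T{i + 1:02d}" for i in range(n)]


def _sample_names(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _null_fractions(n_taxa: int, n_samples: int, concentration: float, rng) -> np.ndarray:
    raw = rng.gamma(concentration, 1.0, size=(n_taxa, n_samples))
    raw = np.maximum(raw, 1e-12)
    return raw / raw.sum(axis=0)


def generate_null(
    n_taxa: int, n_samples: int, seed: int = 0, concentration: float = 1.0
) -> AbundanceMatrix:
    """Background-only community: no planted structure."""
    rng = np.random.default_rng(seed)
    frac = _null_fractions(n_taxa, n_samples, concentration, rng)
    df = pd.DataFrame(frac, index=_taxon_names(n_taxa), columns=_sample_names(n_samples))
    return AbundanceMatrix(df, region_of=_regions(_sample_names(n_samples)))


def _regions(samples: list[str]) -> dict[str, str]:
    half = len(samples) // 2
    return {s: ("A" if i < half else "B") for i, s in enumerate(samples)}


def generate_planted(spec: SyntheticSpec) -> tuple[AbundanceMatrix, InteractionNetwork]:
    """Community with planted triplets, plus the ground-truth network."""
    rng = np.random.default_rng(spec.seed)
    frac = _null_fractions(spec.n_taxa, spec.n_samples, spec.baseline_concentration, rng)
    taxa = _taxon_names(spec.n_taxa)
    samples = _sample_names(spec.n_samples)

    out = frac.copy()
    special = set()
    for t, c, k in spec.planted:
        special.update((t, c, k))

    # Cap every planted row so the planted block can never exhaust a sample:
    # with regulator fractions ≤ B, a target is ≤ 2·beta·B + baseline margin,
    # so B is budgeted to keep all planted rows jointly below ~95% of a
    # sample, leaving the background ≥5%.  This keeps the planted rows exact
    # through closure, so the linear response survives renormalization.
    n_trip = max(len(spec.planted), 1)
    beta = max(spec.beta_coop, spec.beta_comp)
    cap = max((0.95 / n_trip - 0.04) / (2.0 + 2.0 * beta), 0.01)
    for i in special:
        rowmax = out[i].max()
        if rowmax > cap:
            out[i] *= cap / rowmax
    for t, c, k in spec.planted:
        baseline = (
            spec.target_baseline
            if spec.target_baseline is not None
            else spec.beta_comp * out[k].max() + 0.02
        )
        raw = baseline + spec.beta_coop * out[c] - spec.beta_comp * out[k]
        if spec.noise_sd > 0:
            raw = raw + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        out[t] = np.maximum(raw, 1e-6)

    # keep planted rows exact; rescale the untouched background to fill the rest
    background = [i for i in range(spec.n_taxa) if i not in special]
    special_sum = out[sorted(special), :].sum(axis=0) if special else np.zeros(spec.n_samples)
    remaining = 1.0 - special_sum
    if background:
        bg_sum = out[background, :].sum(axis=0)
        ok = remaining > 1e-6
        scale = np.where(ok, remaining / bg_sum, 1.0)
        out[background, :] *= scale
    out /= out.sum(axis=0)  # exact closure; a no-op except in overflow columns

    df = pd.DataFrame(out, index=taxa, columns=samples)
    matrix = AbundanceMatrix(df, region_of=_regions(samples))

    truth = InteractionNetwork()
    for t, c, k in spec.planted:
        for i in (t, c, k):
            truth.add_node(taxa[i])
        truth.add_interaction(taxa[c], taxa[t], COOPERATIVE, 1.0)
        truth.add_interaction(taxa[k], taxa[t], COMPETITIVE, 1.0)
    return matrix, truth


def score_recovery(
    inferred: InteractionNetwork, truth: InteractionNetwork
) -> dict[str, float]:
    """Precision/recall/F1 of inferred signed directed edges against truth."""
    inf = inferred.edge_set()
    tru = truth.edge_set()
    tp = len(inf & tru)
    precision = tp / len(inf) if inf else (1.0 if not tru else 0.0)
    recall = tp / len(tru) if tru else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}
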