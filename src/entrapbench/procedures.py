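"""Reference FDR-control procedures audited by the entrapment framework.

Implements target-decoy competition (TDC) with its q-value inversion, the
PSM-and-peptide double-competition protocol for peptide-level analysis, and
decoy-based empirical p-values fed to Benjamini-Hochberg or Storey's
q-value procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScoredLabel", "TdcResult", "PsmRecord", "PValueSet", "tdc",
    "tdc_qvalues", "psm_and_peptide", "empirical_pvalues", "bh_adjust",
    "storey_qvalues",
]


@dataclass(frozen=True)
class ScoredLabel:
    """A competition winner: score W, label L (+1 target / -1 decoy), id."""

    w: float
    l: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.l not in (1, -1):
            raise ValueError("label must be +1 (target) or -1 (decoy)")


@dataclass
class TdcResult:
    alpha: float
    K: int
    d_k: int
    t_k: int
    reported: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PsmRecord:
    spectrum_id: str
    peptide: str
    peptide_class: str  # "target" | "decoy"
    score: float


@dataclass
class PValueSet:
    pvalues: np.ndarray
    qvalues: np.ndarray
    method: str
    pi0: float = 1.0


def _ranked(pairs: Sequence[ScoredLabel], seed: int) -> list[ScoredLabel]:
    """Sort by decreasing score, ties in random order (seeded)."""
    rng = np.random.default_rng(seed)
    jitter = rng.random(len(pairs))
    order = sorted(range(len(pairs)),
                   key=lambda i: (-pairs[i].w, jitter[i]))
    return [pairs[i] for i in order]


def tdc(pairs: Sequence[ScoredLabel], alpha: float, seed: int = 0) -> TdcResult:
    """Target-decoy competition at FDR level alpha.

    After ranking by decreasing score (ties shuffled), the rejection index K
    is the largest k such that (D_k + 1) / max(T_k, 1) <= alpha, where D_k
    and T_k count decoys and targets among the top k; the reported
    discoveries are the targets among the top K.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ranked = _ranked(pairs, seed)
    K = d_K = t_K = 0
    d = t = 0
    for k, p in enumerate(ranked, start=1):
        if p.l == -1:
            d += 1
        else:
            t += 1
        if (d + 1) / max(t, 1) <= alpha:
            K, d_K, t_K = k, d, t
    reported = [p.id for p in ranked[:K] if p.l == 1]
    return TdcResult(alpha=alpha, K=K, d_k=d_K, t_k=t_K, reported=reported)


def tdc_qvalues(pairs: Sequence[ScoredLabel], seed: int = 0) -> dict[str, float]:
    """Per-target q-values inverting the TDC rule.

    The q-value of the target at rank k is min over k' >= k of
    (D_k' + 1) / max(T_k', 1), capped at 1; thresholding these at alpha
    reproduces ``tdc(pairs, alpha)`` exactly for every alpha.
    """
    ranked = _ranked(pairs, seed)
    n = len(ranked)
    ratios = np.empty(n)
    d = t = 0
    for k, p in enumerate(ranked):
        if p.l == -1:
            d += 1
        else:
            t += 1
        ratios[k] = (d + 1) / max(t, 1)
    qs = np.minimum(np.minimum.accumulate(ratios[::-1])[::-1], 1.0)
    return {p.id: float(qs[k]) for k, p in enumerate(ranked) if p.l == 1}


def psm_and_peptide(psms: Sequence[PsmRecord],
                    pairing: Mapping[str, str], seed: int = 0,
                    ) -> list[ScoredLabel]:
    """Peptide-level double competition over PSMs.

    Stage 1: per spectrum keep the best-scoring PSM (ties random).  Stage 2:
    each peptide scores the max over its surviving PSMs; peptides with no
    PSM score -inf.  Stage 3: within each target-decoy pair (``pairing``
    maps target peptide -> decoy peptide) the higher-scoring peptide wins
    and is emitted as a (score, label) pair, ties broken randomly.
    """
    rng = np.random.default_rng(seed)
    best_by_spectrum: dict[str, PsmRecord] = {}
    tie_key: dict[str, float] = {}
    for psm in psms:
        cur = best_by_spectrum.get(psm.spectrum_id)
        jitter = rng.random()
        if cur is None or psm.score > cur.score or (
                psm.score == cur.score and jitter > tie_key[psm.spectrum_id]):
            best_by_spectrum[psm.spectrum_id] = psm
            tie_key[psm.spectrum_id] = jitter
    peptide_score: dict[str, float] = {}
    known = set(pairing) | set(pairing.values())
    for psm in best_by_spectrum.values():
        if psm.peptide not in known:
            raise ValueError(f"peptide {psm.peptide!r} has no target-decoy pair")
        peptide_score[psm.peptide] = max(
            peptide_score.get(psm.peptide, -math.inf), psm.score)
    out: list[ScoredLabel] = []
    for target, decoy in pairing.items():
        ts = peptide_score.get(target, -math.inf)
        ds = peptide_score.get(decoy, -math.inf)
        if ts > ds or (ts == ds and rng.random() < 0.5):
            out.append(ScoredLabel(w=ts, l=1, id=target))
        else:
            out.append(ScoredLabel(w=ds, l=-1, id=decoy))
    return out


def empirical_pvalues(target_scores: Sequence[float],
                      decoy_scores: Sequence[float], *,
                      pseudo_count: bool = False) -> np.ndarray:
    """Empirical p-value of each target score against the decoy distribution.

    p(t) = #{decoys >= t} / #decoys.  With ``pseudo_count`` the +1-floored
    variant (1 + #{decoys >= t}) / (1 + #decoys) is used, which avoids
    exact zeros at the cost of departing from the plain empirical fraction.
    """
    d = np.sort(np.asarray(decoy_scores, float))
    if d.size == 0:
        raise ValueError("need at least one decoy score")
    t = np.asarray(target_scores, float)
    n_ge = d.size - np.searchsorted(d, t, side="left")
    if pseudo_count:
        return (1.0 + n_ge) / (1.0 + d.size)
    return n_ge / d.size


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def _pi0_smoother(p: np.ndarray, grid: np.ndarray) -> float:
    """Storey-Tibshirani pi0: cubic smoother through pi0(lambda), read at max."""
    pi0_l = np.array([(p > lam).sum() / (p.size * (1.0 - lam)) for lam in grid])
    if grid.size >= 4:
        spline = UnivariateSpline(grid, pi0_l, k=3)
        pi0 = float(spline(grid.max()))
    else:
        pi0 = float(pi0_l[-1])
    return pi0


def storey_qvalues(pvalues: Sequence[float],
                   lambda_grid: float | Sequence[float] | None = None,
                   ) -> PValueSet:
    """Storey q-values with smoother-based pi0 estimation.

    ``lambda_grid`` may be a single lambda (direct estimator
    pi0 = #{p > lambda} / (m * (1 - lambda))) or a grid (default
    0.05..0.95 step 0.05) evaluated through a cubic smoother at the largest
    lambda.  pi0 is clipped to (0, 1]; degenerate p-value distributions
    fall back to pi0 = 1 with a warning.  q-values are the pi0-scaled BH
    cumulative minimum, so pi0 = 1 reproduces BH exactly.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if lambda_grid is None:
        grid = DEFAULT_LAMBDA_GRID
    else:
        grid = np.atleast_1d(np.asarray(lambda_grid, float))
    if grid.size == 1:
        lam = float(grid[0])
        pi0 = (p > lam).sum() / (p.size * (1.0 - lam))
    else:
        pi0 = _pi0_smoother(p, grid)
    if not np.isfinite(pi0) or pi0 <= 0 or (p <= grid.min()).all():
        warnings.warn("degenerate p-value distribution; falling back to "
                      "pi0 = 1", stacklevel=2)
        pi0 = 1.0
    pi0 = min(pi0, 1.0)
    qs = np.minimum(pi0 * bh_adjust(p), 1.0)
    return PValueSet(pvalues=p, qvalues=qs, method="storey", pi0=pi0)
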