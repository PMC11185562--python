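"""Entrapment FDP estimators: combined, lower bound, sample, paired, k-matched.

Notation.  An analysis tool searches a combined database of original targets
(T) and entrapments (E_T) with entrapment-to-target ratio r, and reports
discoveries with q-values.  At an FDR threshold t, let N_T and N_E be the
numbers of original-target and entrapment discoveries.  The estimators of
the false discovery proportion (FDP) are

* combined     N_E * (1 + 1/r) / (N_T + N_E)   -- upper bound in expectation
* lower bound  N_E / (N_T + N_E)               -- lower bound
* sample       (N_E / r) / N_T                 -- estimates the FDP among the
  original-target discoveries only; not a valid bound in either direction
* paired (r = 1, requires target<->entrapment pairing)
      (N_E + N_{E>=s>T} + 2*N_{E>T>=s}) / (N_T + N_E)
  where s is the discovery cutoff score, N_{E>=s>T} counts discovered
  entrapments whose paired target scored below s, and N_{E>T>=s} counts
  discovered entrapments whose paired target was also discovered but scored
  lower.  The paired estimator is an upper bound in expectation that is
  tighter than the combined one.
* k-matched (r = k >= 1): each target is paired with k entrapments and the
  two pair-comparison counts enter with weight 1/k:
      (N_E + (N_{E>=s>T} + 2*N_{E>T>=s}) / k) / (N_T + N_E),
  which reduces exactly to the paired formula at k = 1.

The :class:`EntrapmentModel` / :class:`EntrapmentResults` pair evaluates the
estimators over a grid of FDR thresholds, statsmodels-style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EstimatorInput", "PairedCounts", "DiscoveryTable", "FdpCurve",
    "CoverageBand", "InflationResult", "combined_fdp", "lower_bound_fdp",
    "sample_fdp", "paired_counts", "paired_fdp", "k_matched_fdp",
    "fdp_curve", "coverage_band", "inflation_rate", "direct_fdp",
    "EntrapmentModel", "EntrapmentResults",
]

LABEL_ORIGINAL = "original"
LABEL_ENTRAPMENT = "entrapment"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimatorInput:
    """Count statistics feeding the count-only estimators."""

    n_target: int
    n_entrap: int
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.n_target < 0 or self.n_entrap < 0:
            raise ValueError("counts must be non-negative")
        if self.r <= 0:
            raise ValueError("effective ratio r must be positive")


@dataclass(frozen=True)
class PairedCounts:
    """Pair-comparison counts at cutoff score s (k = pairing multiplicity)."""

    s: float
    n_entrap: int
    n_e_ge_s_t_lt: int   # entrapment discovered, paired target below cutoff
    n_e_gt_t_ge_s: int   # entrapment discovered, paired target discovered but lower
    k: int = 1

    def __post_init__(self) -> None:
        if min(self.n_entrap, self.n_e_ge_s_t_lt, self.n_e_gt_t_ge_s) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_e_ge_s_t_lt + self.n_e_gt_t_ge_s > self.n_entrap:
            raise ValueError("pair-comparison counts exceed entrapment count")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class DiscoveryTable:
    """Scored, labeled discoveries with pairing keys.

    Wraps a DataFrame with canonical columns ``id``, ``label`` (original /
    entrapment), ``score``, ``q_value`` and ``pair_key`` (the identifier of
    the paired original target, empty/NaN for originals and for unpaired
    entrapments).  An optional boolean ``is_false`` column carries ground
    truth in simulations and double-entrapment experiments.
    """

    df: pd.DataFrame

    REQUIRED = ("id", "label", "score", "q_value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"DiscoveryTable missing columns: {missing}")
        bad = set(self.df["label"].unique()) - {LABEL_ORIGINAL, LABEL_ENTRAPMENT}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        q = self.df["q_value"].to_numpy(float)
        finite = q[np.isfinite(q)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("q-values must lie in [0, 1]")
        if "pair_key" not in self.df.columns:
            self.df = self.df.assign(pair_key=pd.NA)

    def __len__(self) -> int:
        return len(self.df)

    def discoveries(self, threshold: float) -> pd.DataFrame:
        return self.df[self.df["q_value"] <= threshold]

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiscoveryTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class FdpCurve:
    """Estimated-FDP-vs-FDR-threshold curves, one column per method."""

    thresholds: np.ndarray
    estimates: dict[str, np.ndarray]
    n_target: np.ndarray
    n_entrap: np.ndarray
    band_half_widths: dict[str, np.ndarray] = field(default_factory=dict)
    uncapped: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame({"threshold": self.thresholds,
                             "n_target": self.n_target,
                             "n_entrap": self.n_entrap})
        for m, v in self.estimates.items():
            base[m] = v
        for m, v in self.band_half_widths.items():
            base[f"{m}_band"] = v
        return base


@dataclass(frozen=True)
class CoverageBand:
    """95% coverage band of a mean of n replicate FDP estimates."""

    n: int
    sigma_n: float
    half_width: float


@dataclass(frozen=True)
class InflationResult:
    """Discovery-count inflation of a tool's 1% FDR list vs the paired-FDP 1% list."""

    n1: int
    n2: int
    rate: float


# ---------------------------------------------------------------------------
# count-only estimators
# ---------------------------------------------------------------------------

def _as_input(inp: EstimatorInput | tuple, r: float | None = None) -> EstimatorInput:
    if isinstance(inp, EstimatorInput):
        return inp
    return EstimatorInput(*inp) if r is None else EstimatorInput(*inp, r=r)


def combined_fdp(inp: EstimatorInput, *, cap: bool = True) -> float:
    """Upper-bound FDP estimate among target+entrapment discoveries."""
    inp = _as_input(inp)
    total = inp.n_target + inp.n_entrap
    if total == 0:
        return 0.0
    est = inp.n_entrap * (1.0 + 1.0 / inp.r) / total
    return min(est, 1.0) if cap else est


def lower_bound_fdp(inp: EstimatorInput) -> float:
    """Lower-bound FDP estimate: entrapment fraction of all discoveries."""
    inp = _as_input(inp)
    total = inp.n_target + inp.n_entrap
    if total == 0:
        return 0.0
    return inp.n_entrap / total


def sample_fdp(inp: EstimatorInput, *, cap: bool = True) -> float:
    """FDP estimate among original-target discoveries only.

    Not a valid bound in either direction; reported for comparison only.
    """
    inp = _as_input(inp)
    if inp.n_entrap == 0:
        return 0.0
    if inp.n_target == 0:
        raise ValueError("sample estimator undefined: no original-target "
                         "discoveries but entrapment discoveries present")
    est = (inp.n_entrap / inp.r) / inp.n_target
    return min(est, 1.0) if cap else est


# ---------------------------------------------------------------------------
# paired / k-matched
# ---------------------------------------------------------------------------

def _pair_scores(table: DiscoveryTable,
                 pairs: Mapping[str, Sequence[str]] | None) -> pd.DataFrame:
    """Resolve each entrapment row's paired original-target score.

    Pairing is taken from the table's ``pair_key`` column; ``pairs`` (a
    target -> entrapments map, e.g. ``PairedEntrapmentDB.pairs``) is used to
    fill missing keys by reverse lookup on the entrapment id.  Originals
    absent from the table score -inf.
    """
    df = table.df
    ent = df[df["label"] == LABEL_ENTRAPMENT].copy()
    if ent.empty:
        ent["pair_score"] = pd.Series(dtype=float)
        return ent
    keys = ent["pair_key"].astype("object").copy()
    if pairs is not None:
        reverse = {e: t for t, ents in pairs.items() for e in ents}
        missing = keys.isna() | (keys == "")
        keys[missing] = ent.loc[missing, "id"].map(reverse)
    unresolved = ent.loc[keys.isna() | (keys == ""), "id"].tolist()
    if unresolved:
        raise ValueError(f"entrapment rows with unresolvable pair keys: "
                         f"{unresolved[:10]}")
    orig = df[df["label"] == LABEL_ORIGINAL]
    score_of = dict(zip(orig["id"], orig["score"].astype(float)))
    ent["pair_score"] = [score_of.get(k, -math.inf) for k in keys]
    return ent


def paired_counts(table: DiscoveryTable,
                  pairs: Mapping[str, Sequence[str]] | None = None,
                  s: float = -math.inf, *, k: int = 1,
                  seed: int = 0) -> PairedCounts:
    """Classify discovered entrapments against their paired targets at cutoff s.

    Every entrapment scoring >= s falls in exactly one bin: paired target
    below the cutoff; paired target discovered but scoring below the
    entrapment; or paired target discovered and scoring above (uncounted).
    Exact entrapment-target score ties are broken by a seeded fair coin.
    """
    ent = _pair_scores(table, pairs)
    disc = ent[ent["score"].astype(float) >= s]
    n_entrap = len(disc)
    e = disc["score"].to_numpy(float)
    t = disc["pair_score"].to_numpy(float)
    rng = np.random.default_rng(seed)
    below_cutoff = t < s
    ties = (e == t) & ~below_cutoff
    ent_wins = e > t
    if ties.any():
        ent_wins = ent_wins.copy()
        ent_wins[ties] = rng.random(int(ties.sum())) < 0.5
    n_e_ge_s_t_lt = int(below_cutoff.sum())
    n_e_gt_t_ge_s = int((~below_cutoff & ent_wins).sum())
    return PairedCounts(s=s, n_entrap=n_entrap, n_e_ge_s_t_lt=n_e_ge_s_t_lt,
                        n_e_gt_t_ge_s=n_e_gt_t_ge_s, k=k)


def paired_fdp(counts: PairedCounts, n_target: int, *, cap: bool = True) -> float:
    """Paired upper-bound FDP estimate (pair multiplicity k = 1)."""
    if counts.k != 1:
        raise ValueError("counts were computed with k != 1; use k_matched_fdp")
    return k_matched_fdp(counts, n_target, cap=cap)


def k_matched_fdp(counts: PairedCounts, n_target: int, *, cap: bool = True) -> float:
    """k-matched generalisation of the paired estimator (k = 1 reduces to it).

    Each of the k entrapments of a target contributes its pair-comparison
    evidence with weight 1/k, keeping the estimator an expected upper bound
    while using the r = k database.
    """
    total = n_target + counts.n_entrap
    if total == 0:
        return 0.0
    num = counts.n_entrap + (counts.n_e_ge_s_t_lt
                             + 2.0 * counts.n_e_gt_t_ge_s) / counts.k
    est = num / total
    return min(est, 1.0) if cap else est


def brute_force_paired_counts(table: DiscoveryTable,
                              pairs: Mapping[str, Sequence[str]] | None = None,
                              s: float = -math.inf, *, k: int = 1,
                              seed: int = 0) -> PairedCounts:
    """Row-by-row reference classifier for :func:`paired_counts` (test oracle)."""
    ent = _pair_scores(table, pairs)
    rng = np.random.default_rng(seed)
    n_entrap = n_lt = n_gt = 0
    for _, row in ent.iterrows():
        e, t = float(row["score"]), float(row["pair_score"])
        if e < s:
            continue
        n_entrap += 1
        if t < s:
            n_lt += 1
        else:
            if e == t:
                if rng.random() < 0.5:
                    n_gt += 1
            elif e > t:
                n_gt += 1
    return PairedCounts(s=s, n_entrap=n_entrap, n_e_ge_s_t_lt=n_lt,
                        n_e_gt_t_ge_s=n_gt, k=k)


# ---------------------------------------------------------------------------
# curves, bands, derived metrics
# ---------------------------------------------------------------------------

def default_threshold_grid(table: DiscoveryTable, n: int = 200) -> np.ndarray:
    """Logarithmic grid from 1e-4 to the largest reported q-value."""
    q = table.df["q_value"].to_numpy(float)
    q = q[np.isfinite(q)]
    hi = float(q.max()) if q.size else 1.0
    hi = max(hi, 1e-4)
    return np.logspace(-4, math.log10(hi), n)


def fdp_curve(table: DiscoveryTable,
              pairs: Mapping[str, Sequence[str]] | None = None,
              methods: Iterable[str] = ("lower", "combined", "paired"),
              thresholds: Sequence[float] | None = None, *,
              r: float = 1.0, k: int = 1, seed: int = 0) -> FdpCurve:
    """Evaluate the requested estimators over a grid of FDR thresholds.

    At each threshold t the discovery set is every row with q-value <= t and
    the paired cutoff score s is the minimum score among those rows.
    """
    if len(table) == 0:
        raise ValueError("empty discovery table")
    methods = list(methods)
    known = {"lower", "combined", "sample", "paired"}
    bad = set(methods) - known
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}; choose from {sorted(known)}")
    if thresholds is None:
        thresholds = default_threshold_grid(table)
    thresholds = np.asarray(sorted(thresholds), float)
    if thresholds.size and (thresholds[0] <= 0 or thresholds[-1] > 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if "paired" in methods and pairs is None and \
            table.df["pair_key"].isna().all():
        raise ValueError("the paired estimator needs target-entrapment "
                         "pairing (pairs map or pair_key column)")

    q = table.df["q_value"].to_numpy(float)
    labels = table.df["label"].to_numpy()
    scores = table.df["score"].to_numpy(float)
    est: dict[str, list[float]] = {m: [] for m in methods}
    raw: dict[str, list[float]] = {m: [] for m in methods}
    nts, nes = [], []
    for t in thresholds:
        disc = q <= t
        n_t = int((labels[disc] == LABEL_ORIGINAL).sum())
        n_e = int((labels[disc] == LABEL_ENTRAPMENT).sum())
        nts.append(n_t)
        nes.append(n_e)
        inp = EstimatorInput(n_t, n_e, r=r) if (n_t + n_e) else None
        for m in methods:
            if inp is None:
                est[m].append(0.0)
                raw[m].append(0.0)
                continue
            if m == "lower":
                v = u = lower_bound_fdp(inp)
            elif m == "combined":
                u = combined_fdp(inp, cap=False)
                v = min(u, 1.0)
            elif m == "sample":
                # undefined when only entrapments are discovered
                u = sample_fdp(inp, cap=False) if (n_t or not n_e) else math.nan
                v = min(u, 1.0)
            else:  # paired / k-matched
                s = float(scores[disc].min())
                counts = paired_counts(table, pairs, s, k=k, seed=seed)
                u = k_matched_fdp(counts, n_t, cap=False)
                v = min(u, 1.0)
            est[m].append(v)
            raw[m].append(u)
    return FdpCurve(thresholds=thresholds,
                    estimates={m: np.asarray(v) for m, v in est.items()},
                    n_target=np.asarray(nts), n_entrap=np.asarray(nes),
                    uncapped={m: np.asarray(v) for m, v in raw.items()})


def coverage_band(fdp_estimates: Sequence[float], *,
                  literal_n: bool = False) -> CoverageBand:
    """95% coverage band half-width for the mean of replicate FDP estimates.

    Default is the standard error of the mean, 1.96 * sd / sqrt(n); with
    ``literal_n`` the divisor is n instead of sqrt(n).
    """
    x = np.asarray(fdp_estimates, float)
    if x.size < 2:
        raise ValueError("need at least 2 replicate estimates")
    sigma = float(np.std(x, ddof=1))
    denom = x.size if literal_n else math.sqrt(x.size)
    return CoverageBand(n=x.size, sigma_n=sigma,
                        half_width=1.96 * sigma / denom)


def inflation_rate(n1: int, n2: int) -> InflationResult:
    """Percent excess of the tool's discovery count over the entrapment-guided one."""
    if n2 <= 0:
        raise ValueError("n2 must be positive")
    return InflationResult(n1=n1, n2=n2, rate=100.0 * (n1 - n2) / n2)


def direct_fdp(table: DiscoveryTable, threshold: float = math.inf,
               false_column: str = "is_false") -> float:
    """Direct FDP from known-false flags (double-entrapment experiments)."""
    if false_column not in table.df.columns:
        raise ValueError(f"table has no {false_column!r} column")
    disc = table.df[table.df["q_value"] <= threshold]
    if disc.empty:
        raise ValueError("empty discovery set")
    return float(disc[false_column].astype(bool).mean())


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class EntrapmentModel:
    """Entrapment FDP estimation for one tool's discovery list.

    Parameters
    ----------
    table:
        Discoveries with labels, scores and tool q-values.
    pairs:
        Target -> entrapments map (``PairedEntrapmentDB.pairs``); required
        for the paired/k-matched estimator unless the table carries
        ``pair_key``.
    r:
        Effective entrapment-to-target database ratio.
    k:
        Pairing multiplicity for the k-matched estimator (k = r for
        shuffled databases built with that multiplicity).
    """

    def __init__(self, table: DiscoveryTable,
                 pairs: Mapping[str, Sequence[str]] | None = None, *,
                 r: float = 1.0, k: int = 1, seed: int = 0):
        self.table = table
        self.pairs = pairs
        self.r = float(r)
        self.k = int(k)
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EntrapmentModel":
        return cls(DiscoveryTable(df), **kwargs)

    def fit(self, thresholds: Sequence[float] | None = None,
            methods: Iterable[str] = ("lower", "combined", "paired"),
            ) -> "EntrapmentResults":
        curve = fdp_curve(self.table, self.pairs, methods, thresholds,
                          r=self.r, k=self.k, seed=self.seed)
        return EntrapmentResults(self, curve)


class EntrapmentResults:
    """Fitted estimator curves with convenience diagnostics."""

    def __init__(self, model: EntrapmentModel, curve: FdpCurve):
        self.model = model
        self.curve = curve

    @property
    def frame(self) -> pd.DataFrame:
        return self.curve.to_frame()

    def estimate_at(self, method: str, threshold: float) -> float:
        """Estimated FDP at the largest grid threshold <= ``threshold``."""
        idx = np.searchsorted(self.curve.thresholds, threshold, side="right") - 1
        if idx < 0:
            raise ValueError(f"threshold {threshold} below the fitted grid")
        return float(self.curve.estimates[method][idx])

    def inflation(self, fdr_threshold: float = 0.01,
                  method: str = "paired") -> InflationResult:
        """Discovery inflation of the tool's list vs the entrapment-guided list.

        n1 counts discoveries at the tool's ``fdr_threshold``; n2 counts
        discoveries at the largest threshold where the requested estimator
        stays <= ``fdr_threshold``.
        """
        q = self.model.table.df["q_value"].to_numpy(float)
        n1 = int((q <= fdr_threshold).sum())
        est = self.curve.estimates[method]
        ok = np.nonzero(est <= fdr_threshold)[0]
        if ok.size == 0:
            raise ValueError(f"{method} estimate never falls below "
                             f"{fdr_threshold}; no guided cutoff exists")
        t2 = self.curve.thresholds[ok[-1]]
        n2 = int((q <= t2).sum())
        return inflation_rate(n1, n2)

    def summary(self, thresholds: Sequence[float] = (0.01, 0.05, 0.1)) -> str:
        lines = [
            "Entrapment FDP estimation",
            "=" * 58,
            f"rows: {len(self.model.table)}   r: {self.model.r:g}   "
            f"k: {self.model.k}",
            f"methods: {', '.join(self.curve.estimates)}",
            "-" * 58,
            "threshold  " + "".join(f"{m:>12}" for m in self.curve.estimates)
            + "   N_T   N_E",
        ]
        for t in thresholds:
            idx = np.searchsorted(self.curve.thresholds, t, side="right") - 1
            if idx < 0:
                continue
            vals = "".join(f"{self.curve.estimates[m][idx]:12.4f}"
                           for m in self.curve.estimates)
            lines.append(f"{t:9.3g}  {vals}  {self.curve.n_target[idx]:>4}  "
                         f"{self.curve.n_entrap[idx]:>4}")
        lines.append("-" * 58)
        lines.append("sample estimator, if shown, is not a valid bound in "
                     "either direction")
        return "\n".join(lines)
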