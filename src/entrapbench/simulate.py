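"""Synthetic search results with known ground truth (equal-chance model).

The simulator emulates a peptide-level analysis of a combined
target+entrapment database under the exchangeability assumption the
entrapment estimators rely on: peptides truly present in the sample
("native") draw scores from a signal distribution (with a per-peptide
detection probability), while absent original targets, every entrapment
peptide, and every decoy draw i.i.d. scores from one shared null
distribution.  Each database peptide competes against its own decoy
(PSM-and-peptide style) and the winners receive TDC q-values, yielding a
discovery table whose true false-discovery proportion is known exactly.

``bound_experiment`` repeats this over many replicates -- redrawing all
entrapment and decoy scores each time, which emulates redrawing the random
databases themselves -- and checks the direction of each estimator's bound
against the known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .estimators import (
    DiscoveryTable,
    EstimatorInput,
    PairedCounts,
    combined_fdp,
    k_matched_fdp,
    lower_bound_fdp,
    sample_fdp,
)

__all__ = ["SimConfig", "SimulatedSearch", "simulate_search", "true_fdp",
           "bound_experiment", "exchangeability_audit"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated entrapment experiment.

    Scores are in arbitrary calibrated units; the null is shared by absent
    targets, entrapments and decoys (the exchangeability the estimators
    assume), and natives yield a score at all with probability
    ``detect_prob``.  ``r`` is the (integer) number of entrapment peptides
    paired with each original target; ``k_matched`` is the pairing
    multiplicity used by the paired/k-matched estimator and must equal
    ``r`` when greater than 1.
    """

    n_native: int = 1000
    n_absent: int = 4000
    r: int = 1
    k_matched: int = 1
    signal_mean: float = 4.0
    signal_sd: float = 1.0
    null_mean: float = 0.0
    null_sd: float = 1.0
    detect_prob: float = 0.7
    score_model: str = "gaussian"  # or "gumbel" (heavy-tailed null)
    n_replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_native, self.n_absent) < 0 or self.r < 1:
            raise ValueError("counts must be non-negative and r >= 1")
        if self.signal_sd <= 0 or self.null_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 <= self.detect_prob <= 1:
            raise ValueError("detect_prob must lie in [0, 1]")
        if self.k_matched > 1 and self.k_matched != self.r:
            raise ValueError("k_matched > 1 requires r == k_matched")
        if self.score_model not in ("gaussian", "gumbel"):
            raise ValueError("score_model must be 'gaussian' or 'gumbel'")


#: Double-entrapment study conditions: the "original target" database is
#: dominated by known-false foreign peptides (native minority), so the
#: direct estimate -- counting every foreign or entrapment discovery as
#: false -- equals the true FDP and can validate the paired estimator
#: itself.  Scaled to desk size while preserving the native-minority regime.
DOUBLE_ENTRAPMENT_CONFIG = SimConfig(n_native=500, n_absent=25000, r=1,
                                     n_replicates=100)


@dataclass
class SimulatedSearch:
    """One simulated search: discovery table plus ground truth."""

    table: DiscoveryTable
    pairs: dict[str, list[str]]
    config: SimConfig
    arrays: dict = field(default_factory=dict, repr=False)


def _null(rng: np.random.Generator, size, cfg: SimConfig) -> np.ndarray:
    if cfg.score_model == "gumbel":
        return rng.gumbel(cfg.null_mean, cfg.null_sd, size)
    return rng.normal(cfg.null_mean, cfg.null_sd, size)


def _signal(rng: np.random.Generator, size, cfg: SimConfig) -> np.ndarray:
    if cfg.score_model == "gumbel":
        return rng.gumbel(cfg.signal_mean, cfg.signal_sd, size)
    return rng.normal(cfg.signal_mean, cfg.signal_sd, size)


def _draw_replicate(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Draw all scores and run the decoy competition + TDC q-values.

    Returns flat arrays over database peptides (targets first, then the r
    blocks of entrapments): score, won (beat its decoy), q (q-value of the
    winning pair, only meaningful where won), is_entrap, is_false, and
    target_index mapping each entrapment to its paired target.
    """
    n_t = cfg.n_native + cfg.n_absent
    target_scores = np.full(n_t, -math.inf)
    detected = rng.random(cfg.n_native) < cfg.detect_prob
    target_scores[:cfg.n_native][detected] = _signal(
        rng, int(detected.sum()), cfg)
    target_scores[cfg.n_native:] = _null(rng, cfg.n_absent, cfg)
    entrap_scores = _null(rng, n_t * cfg.r, cfg)  # r blocks of n_t

    w_db = np.concatenate([target_scores, entrap_scores])
    n_db = w_db.size
    w_decoy = _null(rng, n_db, cfg)
    won = w_db > w_decoy  # continuous scores: ties have measure zero
    w_pair = np.maximum(w_db, w_decoy)

    # TDC q-values over the ranked pair winners
    order = np.argsort(-w_pair, kind="stable")
    is_target_win = won[order]
    d = np.cumsum(~is_target_win)
    t = np.cumsum(is_target_win)
    ratios = (d + 1) / np.maximum(t, 1)
    q_ranked = np.minimum(np.minimum.accumulate(ratios[::-1])[::-1], 1.0)
    q = np.empty(n_db)
    q[order] = q_ranked

    is_entrap = np.zeros(n_db, bool)
    is_entrap[n_t:] = True
    is_false = np.ones(n_db, bool)
    is_false[:cfg.n_native] = False
    target_index = np.tile(np.arange(n_t), cfg.r)
    return {"n_t": n_t, "w_db": w_db, "won": won, "q": q,
            "is_entrap": is_entrap, "is_false": is_false,
            "target_index": target_index}


def simulate_search(config: SimConfig) -> SimulatedSearch:
    """One simulated search, reported as a DiscoveryTable of winners."""
    rng = np.random.default_rng(config.seed)
    a = _draw_replicate(config, rng)
    n_t, r = a["n_t"], config.r
    target_ids = np.array([f"T{i:06d}" for i in range(n_t)])
    ent_ids = np.array([f"E{j + 1}_T{i:06d}"
                        for j in range(r) for i in range(n_t)])
    ids = np.concatenate([target_ids, ent_ids])
    pair_key = np.concatenate(
        [np.full(n_t, "", object), target_ids[a["target_index"]]])
    won = a["won"]
    df = pd.DataFrame({
        "id": ids[won],
        "label": np.where(a["is_entrap"][won], "entrapment", "original"),
        "score": a["w_db"][won],
        "q_value": a["q"][won],
        "pair_key": pair_key[won],
        "is_false": a["is_false"][won],
    })
    pairs = {target_ids[i]: [f"E{j + 1}_T{i:06d}" for j in range(r)]
             for i in range(n_t)}
    return SimulatedSearch(table=DiscoveryTable(df), pairs=pairs,
                           config=config, arrays=a)


def true_fdp(search: SimulatedSearch, threshold: float) -> float:
    """Known FDP of the discovery list at the given q-value threshold."""
    disc = search.table.discoveries(threshold)
    if disc.empty:
        return 0.0
    return float(disc["is_false"].mean())


def _replicate_estimates(cfg: SimConfig, a: dict, alphas: Sequence[float],
                         ) -> list[dict]:
    """All estimators + truth for one replicate at each alpha (array path)."""
    n_t, k = a["n_t"], max(cfg.k_matched, 1)
    won, q, w = a["won"], a["q"], a["w_db"]
    is_entrap, is_false = a["is_entrap"], a["is_false"]
    tgt_idx = a["target_index"]
    # a target's score as seen in the discovery table: -inf if it lost
    tgt_table_score = np.where(won[:n_t], w[:n_t], -math.inf)
    ent_won = won[n_t:]
    ent_scores = w[n_t:]
    ent_q = q[n_t:]
    ent_pair_score = tgt_table_score[tgt_idx]
    rows = []
    for alpha in alphas:
        disc = won & (q <= alpha)
        n_disc = int(disc.sum())
        n_e = int((disc & is_entrap).sum())
        n_tgt = n_disc - n_e
        truth = float(is_false[disc].mean()) if n_disc else 0.0
        if n_disc:
            s = float(w[disc].min())
            inp = EstimatorInput(n_tgt, n_e, r=cfg.r)
            lower = lower_bound_fdp(inp)
            comb = combined_fdp(inp)
            samp = sample_fdp(inp) if (n_tgt or not n_e) else math.nan
            ent_disc = ent_won & (ent_q <= alpha)
            ps = ent_pair_score[ent_disc]
            es = ent_scores[ent_disc]
            counts = PairedCounts(
                s=s, n_entrap=n_e, n_e_ge_s_t_lt=int((ps < s).sum()),
                n_e_gt_t_ge_s=int(((ps >= s) & (es > ps)).sum()), k=k)
            paired = k_matched_fdp(counts, n_tgt)
        else:
            lower = comb = samp = paired = 0.0
        rows.append({"alpha": alpha, "true_fdp": truth, "lower": lower,
                     "combined": comb, "sample": samp, "paired": paired,
                     "n_discoveries": n_disc})
    return rows


def bound_experiment(config: SimConfig,
                     alphas: Sequence[float] = (0.01, 0.05, 0.1),
                     ) -> pd.DataFrame:
    """Monte-Carlo check of every estimator's bound direction.

    Runs ``config.n_replicates`` independent replicates (all null scores --
    entrapments, decoys, absent targets -- are redrawn each time) and
    summarises, per FDR level alpha: the mean and standard error of the
    true FDP and of each estimate, the 95% coverage-band half-width of each
    mean, and pass/fail of the directional checks, each assessed on the
    paired per-replicate differences at two standard errors:

    * ``lower_ok``      mean(lower)    <= mean(true FDP) + 2 SE
    * ``combined_ok``   mean(combined) >= mean(true FDP) - 2 SE
    * ``paired_ok``     mean(paired)   >= mean(true FDP) - 2 SE
    * ``paired_le_combined_ok``  mean(paired) <= mean(combined) + 2 SE
    * ``tdc_ok``        mean(true FDP) <= alpha + 2 SE  (TDC FDR control)
    * ``paired_vs_direct_ok``  |mean(paired) - mean(direct)| <= 2 SE, the
      double-entrapment agreement check (the direct estimate counts every
      known-false discovery, which here is exactly the true FDP).
    """
    if config.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(config.seed)
    per_rep: list[list[dict]] = []
    for _ in range(config.n_replicates):
        a = _draw_replicate(config, rng)
        per_rep.append(_replicate_estimates(config, a, alphas))
    out = []
    n = config.n_replicates
    for j, alpha in enumerate(alphas):
        rep = pd.DataFrame([per_rep[i][j] for i in range(n)])
        row: dict = {"alpha": alpha, "n_replicates": n,
                     "mean_discoveries": rep["n_discoveries"].mean()}
        for m in ("true_fdp", "lower", "combined", "paired", "sample"):
            x = rep[m].dropna()
            row[f"{m}_mean"] = x.mean()
            row[f"{m}_se"] = x.std(ddof=1) / math.sqrt(len(x))
            row[f"{m}_band"] = 1.96 * row[f"{m}_se"]

        def diff_ok(a_col: str, b_col: str, sign: int) -> bool:
            d = (rep[a_col] - rep[b_col]).dropna()
            se = d.std(ddof=1) / math.sqrt(len(d))
            return bool(sign * d.mean() <= 2 * se)

        row["lower_ok"] = diff_ok("lower", "true_fdp", +1)
        row["combined_ok"] = diff_ok("true_fdp", "combined", +1)
        row["paired_ok"] = diff_ok("true_fdp", "paired", +1)
        row["paired_le_combined_ok"] = diff_ok("paired", "combined", +1)
        row["tdc_ok"] = bool(row["true_fdp_mean"]
                             <= alpha + 2 * row["true_fdp_se"])
        d = (rep["paired"] - rep["true_fdp"]).dropna()
        se = d.std(ddof=1) / math.sqrt(len(d))
        row["paired_vs_direct_ok"] = bool(abs(d.mean()) <= 2 * se)
        out.append(row)
    return pd.DataFrame(out)


def exchangeability_audit(config: SimConfig, n_replicates: int = 100,
                          level: float = 0.01) -> float:
    """Generator sanity check: absent-target vs entrapment null scores.

    Runs a two-sample Mann-Whitney test per replicate between the pooled
    absent-target scores and the entrapment scores; returns the fraction of
    replicates in which the test does *not* reject at ``level`` (should be
    close to 1 - level when the generator is exchangeable).
    """
    rng = np.random.default_rng(config.seed)
    passed = 0
    for _ in range(n_replicates):
        a = _draw_replicate(config, rng)
        n_t = a["n_t"]
        absent = a["w_db"][config.n_native:n_t]
        entrap = a["w_db"][n_t:]
        p = mannwhitneyu(absent, entrap, alternative="two-sided").pvalue
        passed += p > level
    return passed / n_replicates
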