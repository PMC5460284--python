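"""Permutation-based integrative differential-expression statistic.

For each feature (gene or peptide) two statistics are computed on log2
values: the pooled-variance Student t (condition minus control) and the
log2-median-ratio (difference of group medians).  Their null
distributions are estimated by recomputing both statistics under random
sample-label permutations, pooled across features.  Each observed
statistic receives a two-tailed empirical p with the add-one rule, the
two p's are combined into a signed Stouffer z, and — because the two
statistics are strongly dependent, which makes the normal-theory
combined p anticonservative — the combined z is referred to its own
permutation null to give the overall p used for selection.  The
closed-form Stouffer p is reported alongside.

Selection rules: a DEG needs overall p below the cut and |log2-median-
ratio| at or above the chosen percentile of the signed permutation null
of the ratio (a data-dependent cutoff); a DEpeptide uses a fixed
fold-change cut (default 0.58 log2 = 1.5-fold); a DEP is a protein with
at least ``min_unique`` same-direction proteotypic DEpeptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateDesignError, InputError


@dataclass
class GroupDesign:
    """Two-group sample design (control vs condition)."""

    samples: list[str]
    groups: list[str]
    control: str
    condition: str

    @classmethod
    def from_frame(cls, design: pd.DataFrame, control: str, condition: str,
                   sample_col: str | None = None) -> "GroupDesign":
        col = sample_col or ("run_id" if "run_id" in design.columns else "sample")
        sub = design[design["group"].isin([control, condition])]
        return cls(samples=list(sub[col]), groups=list(sub["group"]),
                   control=control, condition=condition)

    def validate(self) -> None:
        labels = set(self.groups)
        if labels != {self.control, self.condition}:
            raise InputError(f"design must contain exactly groups "
                             f"{self.control!r} and {self.condition!r}")
        if self.groups.count(self.control) < 2 or self.groups.count(self.condition) < 2:
            raise InputError("need >= 2 samples per group")

    def masks(self, columns) -> tuple[np.ndarray, np.ndarray]:
        by_sample = dict(zip(self.samples, self.groups))
        missing = [c for c in columns if c not in by_sample]
        if missing:
            raise InputError(f"samples missing from design: {missing}")
        grp = np.array([by_sample[c] for c in columns])
        return grp == self.control, grp == self.condition


@dataclass
class NullDistributions:
    """Pooled permutation nulls of both statistics (aligned pairs)."""

    null_t: np.ndarray       # (n_permutations, n_features)
    null_ratio: np.ndarray   # same shape, aligned with null_t
    n_permutations: int
    seed: int
    features: list = field(default_factory=list)

    def t_pool(self) -> np.ndarray:
        pool = self.null_t.ravel()
        return pool[~np.isnan(pool)]

    def ratio_pool(self) -> np.ndarray:
        pool = self.null_ratio.ravel()
        return pool[~np.isnan(pool)]


def _two_group_stats(values: np.ndarray, mask_ctrl: np.ndarray, mask_cond: np.ndarray):
    """Vectorized t and log2-median-ratio for a feature x sample array.

    NaN-aware: features with fewer than 2 observed values in either group
    get NaN t; the ratio needs at least one observed value per group.
    Zero pooled variance with equal medians of the means gives t = 0;
    with unequal means the t is +/-inf here and replaced by the caller.
    """
    a = values[:, mask_ctrl]
    b = values[:, mask_cond]
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        zero_var = sp2 == 0
        t = np.where(zero_var & (m2 == m1), 0.0, t)
        ratio = np.nanmedian(b, axis=1) - np.nanmedian(a, axis=1)
    bad = (n1 < 2) | (n2 < 2)
    t[bad] = np.nan
    ratio[(n1 < 1) | (n2 < 1)] = np.nan
    return t, ratio


def compute_statistics(matrix: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Observed t and log2-median-ratio per feature (log2 input).

    Features without >= 2 observed values per group are marked
    untestable (NaN statistics).  Zero-pooled-variance features with
    unequal means are flagged; their t is set to the largest finite |t|
    observed in the matrix (sign preserved).
    """
    design.validate()
    mask_ctrl, mask_cond = design.masks(matrix.columns)
    t, ratio = _two_group_stats(matrix.to_numpy(dtype=float), mask_ctrl, mask_cond)
    inf = np.isinf(t)
    var_flag = inf.copy()
    if inf.any():
        finite = np.abs(t[np.isfinite(t)])
        cap = float(finite.max()) if finite.size else 1.0
        t[inf] = np.sign(t[inf]) * cap
    return pd.DataFrame(
        {
            "t_value": t,
            "log2_median_ratio": ratio,
            "testable": ~np.isnan(t),
            "zero_variance": var_flag,
        },
        index=matrix.index,
    )


def build_null(
    matrix: pd.DataFrame,
    design: GroupDesign,
    n_permutations: int = 1000,
    seed: int = 0,
) -> NullDistributions:
    """Pooled permutation null of both statistics.

    Label permutations are sampled with replacement from the permutation
    space (one independent draw per iteration, seeded); both statistics
    are recomputed for every feature and pooled across features and
    permutations.
    """
    design.validate()
    mask_ctrl, mask_cond = design.masks(matrix.columns)
    n_ctrl = int(mask_ctrl.sum())
    n_samples = len(matrix.columns)
    if n_samples < 4 or min(n_ctrl, n_samples - n_ctrl) < 2:
        raise DegenerateDesignError("permutation null needs >= 2 samples per group")
    values = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null_t = np.empty((n_permutations, len(matrix)))
    null_r = np.empty((n_permutations, len(matrix)))
    for p in range(n_permutations):
        perm = rng.permutation(n_samples)
        mc = np.zeros(n_samples, dtype=bool)
        mc[perm[:n_ctrl]] = True
        t, r = _two_group_stats(values, mc, ~mc)
        t[np.isinf(t)] = np.nan
        null_t[p] = t
        null_r[p] = r
    return NullDistributions(null_t=null_t, null_ratio=null_r,
                             n_permutations=n_permutations, seed=seed,
                             features=list(matrix.index))


def empirical_p(observed, null_pool) -> np.ndarray | float:
    """Two-tailed empirical p with the add-one rule.

    p = (#{|null| >= |observed|} + 1) / (pool size + 1); never zero.
    """
    pool = np.sort(np.abs(np.asarray(null_pool, dtype=float)))
    if pool.size == 0:
        raise InputError("empty null pool")
    obs = np.abs(np.asarray(observed, dtype=float))
    idx = np.searchsorted(pool, obs, side="left")
    p = (pool.size - idx + 1.0) / (pool.size + 1.0)
    return float(p) if np.isscalar(observed) else p


def stouffer_combine(p_t, p_ratio, sign_t=1.0, sign_ratio=1.0):
    """Closed-form signed Stouffer combination of two two-tailed p's.

    z_i = sign(stat_i) * Phi^-1(1 - p_i/2); z = (z_t + z_ratio)/sqrt(2);
    p = 2 * (1 - Phi(|z|)), clipped into (0, 1].  Concordant statistics
    reinforce; discordant ones cancel.  Returns ``(z, p)``.
    """
    p_t = np.asarray(p_t, dtype=float)
    p_ratio = np.asarray(p_ratio, dtype=float)
    if np.any(p_t <= 0) or np.any(p_ratio <= 0) or np.any(p_t > 1) or np.any(p_ratio > 1):
        raise InputError("p values must lie in (0, 1]")
    z_t = np.sign(sign_t) * norm.isf(p_t / 2.0)
    z_r = np.sign(sign_ratio) * norm.isf(p_ratio / 2.0)
    z = (z_t + z_r) / np.sqrt(2.0)
    p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    if p_t.ndim == 0:
        return float(z), float(p)
    return z, p


def _combined_z(t, ratio, t_pool_sorted, r_pool_sorted):
    def emp(obs, pool):
        idx = np.searchsorted(pool, np.abs(obs), side="left")
        return (pool.size - idx + 1.0) / (pool.size + 1.0)
    z_t = np.sign(t) * norm.isf(emp(t, t_pool_sorted) / 2.0)
    z_r = np.sign(ratio) * norm.isf(emp(ratio, r_pool_sorted) / 2.0)
    return (z_t + z_r) / np.sqrt(2.0)


@dataclass
class DETestResult:
    results: pd.DataFrame
    null: NullDistributions
    design: GroupDesign


def de_test(
    matrix: pd.DataFrame,
    design: GroupDesign,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DETestResult:
    """Full integrative test for every feature of a log2 matrix.

    The result frame carries both the closed-form Stouffer p
    (``p_stouffer``) and the permutation-calibrated overall p
    (``p_overall``) that the selection rules consume; untestable
    features keep NaN statistics and ``testable = False``.
    """
    observed = compute_statistics(matrix, design)
    testable = observed.index[observed["testable"]]
    sub = matrix.loc[testable]
    null = build_null(sub, design, n_permutations=n_permutations, seed=seed)

    t_pool = np.sort(np.abs(null.t_pool()))
    r_pool = np.sort(np.abs(null.ratio_pool()))
    t_obs = observed.loc[testable, "t_value"].to_numpy()
    r_obs = observed.loc[testable, "log2_median_ratio"].to_numpy()
    p_t = empirical_p(t_obs, t_pool)
    p_r = empirical_p(r_obs, r_pool)
    z_obs = _combined_z(t_obs, r_obs, t_pool, r_pool)
    _, p_param = stouffer_combine(p_t, p_r, np.sign(t_obs), np.sign(r_obs))

    nt = null.null_t.ravel()
    nr = null.null_ratio.ravel()
    ok = ~(np.isnan(nt) | np.isnan(nr))
    z_null = np.sort(np.abs(_combined_z(nt[ok], nr[ok], t_pool, r_pool)))
    idx = np.searchsorted(z_null, np.abs(z_obs), side="left")
    p_overall = (z_null.size - idx + 1.0) / (z_null.size + 1.0)

    results = observed.copy()
    for col in ("p_t", "p_ratio", "p_stouffer", "p_overall"):
        results[col] = np.nan
    results.loc[testable, "p_t"] = p_t
    results.loc[testable, "p_ratio"] = p_r
    results.loc[testable, "p_stouffer"] = p_param
    results.loc[testable, "p_overall"] = p_overall
    sign = np.sign(results["log2_median_ratio"])
    results["direction"] = np.select([sign > 0, sign < 0], ["up", "down"], default="none")
    results.loc[~results["testable"], "direction"] = "none"
    return DETestResult(results=results, null=null, design=design)


def select_degs(
    de: DETestResult | pd.DataFrame,
    null_ratio_pool: np.ndarray | None = None,
    p_cut: float = 0.05,
    percentile: float = 95.0,
) -> tuple[pd.DataFrame, float]:
    """DEG rule: overall p below the cut and |log2-median-ratio| at or
    above the given percentile of the signed permutation null of the
    ratio (data-dependent; the original study's data put it at 0.42).

    Returns ``(annotated results, fc_cutoff)``; the ``is_de`` flag is
    added to a copy of the result frame.
    """
    if isinstance(de, DETestResult):
        results = de.results
        pool = de.null.ratio_pool() if null_ratio_pool is None else null_ratio_pool
    else:
        results = de
        if null_ratio_pool is None:
            raise InputError("need the null ratio pool to place the fold-change cutoff")
        pool = null_ratio_pool
    fc_cutoff = float(np.percentile(np.asarray(pool, dtype=float), percentile))
    out = results.copy()
    out["fc_cutoff_used"] = fc_cutoff
    out["is_de"] = (
        out["testable"]
        & (out["p_overall"] < p_cut)
        & (out["log2_median_ratio"].abs() >= fc_cutoff)
    )
    return out, fc_cutoff


def select_depeptides(
    results: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 0.58
) -> pd.DataFrame:
    """DEpeptide rule: overall p < p_cut and |log2-median-ratio| >= fc_cut."""
    out = results.copy()
    out["fc_cutoff_used"] = fc_cut
    out["is_de"] = (
        out["testable"]
        & (out["p_overall"] < p_cut)
        & (out["log2_median_ratio"].abs() >= fc_cut)
    )
    return out


def select_deps(
    depeptides: pd.DataFrame,
    peptide_meta: pd.DataFrame,
    min_unique: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll DEpeptides up to differentially expressed proteins.

    Counts, per protein and direction, the distinct proteotypic
    DEpeptide sequences; a protein is a DEP when one direction reaches
    ``min_unique``.  Proteins reaching it in both directions are
    conflicts: excluded from the DEP list and reported separately.

    ``peptide_meta`` maps peptide_seq -> (protein_ids, proteotypic).
    Returns ``(deps, conflicts)``.
    """
    meta = peptide_meta.set_index("peptide_seq") if "peptide_seq" in peptide_meta.columns else peptide_meta
    de = depeptides[depeptides["is_de"]]
    counts: dict[str, dict[str, set]] = {}
    for seq, row in de.iterrows():
        if seq not in meta.index or not bool(meta.at[seq, "proteotypic"]):
            continue
        prots = meta.at[seq, "protein_ids"]
        protein = prots[0] if len(prots) else None
        if protein is None:
            continue
        counts.setdefault(protein, {"up": set(), "down": set()})
        if row["direction"] in ("up", "down"):
            counts[protein][row["direction"]].add(seq)
    dep_rows, conflict_rows = [], []
    for protein in sorted(counts):
        n_up = len(counts[protein]["up"])
        n_down = len(counts[protein]["down"])
        up_ok, down_ok = n_up >= min_unique, n_down >= min_unique
        if up_ok and down_ok:
            conflict_rows.append((protein, n_up, n_down))
        elif up_ok or down_ok:
            dep_rows.append((protein, "up" if up_ok else "down", n_up, n_down))
    deps = pd.DataFrame(dep_rows, columns=["protein_id", "direction", "n_up", "n_down"])
    conflicts = pd.DataFrame(conflict_rows, columns=["protein_id", "n_up", "n_down"])
    return deps, conflicts
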