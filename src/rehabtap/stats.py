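"""Statistical battery for the two-group longitudinal design.

The design is one between-subject factor (therapy group) crossed with
one within-subject factor (measurement session).  This module provides:

* :func:`mixed_anova` — the univariate mixed-design ANOVA with full SS
  decomposition, Mauchly's sphericity test, Greenhouse–Geisser ε and
  ε-corrected p values, and generalized eta squared η²G;
* :func:`tukey_hsd` — studentized-range post-hoc contrasts on fitted
  cell means;
* :func:`fisher_exact_2x2`, :func:`mann_whitney`, :func:`welch_t`,
  :func:`friedman_test` — the exact / nonparametric battery used for
  baseline tables and ordinal mood ratings;
* :func:`assign_minimized` — covariate-adaptive minimization for
  quasi-random group allocation of small accrual batches;
* :func:`log_transform_outcomes` — natural-log transform of positive
  outcome columns ahead of parametric analysis.

Conventions: Mauchly's test gates the headline p at α = 0.05 (both the
uncorrected and the GG-corrected p are always reported); η²G divides the
effect SS by the effect SS plus *all* subject-level error SS, the
design-robust generalized effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "MannWhitneyResult",
    "mann_whitney",
    "WelchResult",
    "welch_t",
    "FriedmanResult",
    "friedman_test",
    "AnovaResult",
    "mixed_anova",
    "tukey_hsd",
    "AssignmentState",
    "assign_minimized",
    "log_transform_outcomes",
]


# ---------------------------------------------------------------------------
# Exact and nonparametric battery


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 counts, rows = category, columns = group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Uses the "probability at most that of the observed table" rule: the
    p value sums the hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's (the convention of R's ``fisher.test``).
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise ValueError("table must be 2×2")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
                raise ValueError("counts must be non-negative integers")
            arr = np.round(arr).astype(int)
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


@dataclass(frozen=True)
class MannWhitneyResult:
    W: float  # rank-sum statistic for the first sample (U form)
    Z: float  # tie- and continuity-corrected normal deviate
    p: float  # two-sided


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Mann–Whitney rank test with tie and continuity corrections.

    W is the U statistic of the first sample (the form printed by R's
    ``wilcox.test``); Z is the signed normal approximation deviate with
    mid-rank tie correction of the variance and a 0.5 continuity
    correction; p is two-sided from Z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    W = r1 - n1 * (n1 + 1) / 2.0  # U for x
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return MannWhitneyResult(W=float(W), Z=0.0, p=1.0)
    diff = W - mu
    cc = 0.5 * np.sign(diff)
    Z = float((diff - cc) / math.sqrt(var)) if diff != 0 else 0.0
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(Z))))
    return MannWhitneyResult(W=float(W), Z=Z, p=p)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float  # Welch–Satterthwaite, fractional
    p: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Unequal-variance t test with Welch–Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float


def friedman_test(ratings: np.ndarray) -> FriedmanResult:
    """Friedman rank test on a complete subjects × conditions block.

    Rank-based χ² with mid-rank tie correction, df = k − 1.  A block
    with identical ratings across conditions contributes tied ranks; a
    fully constant table gives χ² = 0 and p = 1.
    """
    data = np.asarray(ratings, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("ratings must be a 2-D subjects × conditions array with k >= 2")
    if np.isnan(data).any():
        raise ValueError("incomplete block design: missing cells are not allowed")
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    # tie correction (same as scipy.stats.friedmanchisquare)
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    c = 1.0 - ties / (k * (k * k - 1) * n)
    if c == 0:  # every row completely tied
        return FriedmanResult(chi2=0.0, df=k - 1, p=1.0)
    col_ranksum = ranks.sum(axis=0)
    chi2 = (12.0 / (n * k * (k + 1)) * (col_ranksum**2).sum() - 3 * n * (k + 1)) / c
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return FriedmanResult(chi2=float(chi2), df=k - 1, p=p)


# ---------------------------------------------------------------------------
# Mixed-design ANOVA


@dataclass(frozen=True)
class AnovaResult:
    """Mixed ANOVA results: one row per effect in ``table``.

    ``table`` columns: effect, ss, df1, df2, ms, f, p_unc, mauchly_w,
    mauchly_p, gg_eps, df1_gg, df2_gg, p_gg, p_headline, eta2_g.  For
    the between-subject effect (no sphericity issue) and for k = 2
    within levels (sphericity holds trivially, ε = 1) p_gg equals p_unc.
    ``ss_subject`` and ``ss_error_within`` are the two error strata;
    ``ss_total`` checks the conservation Σ SS = SS_total.
    """

    table: pd.DataFrame
    ss_subject: float
    ss_error_within: float
    ss_total: float
    cell_means: pd.DataFrame
    n_per_group: Dict[str, int]

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}")
        return rows.iloc[0]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1) × k orthonormal contrast matrix (rows sum to zero)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _mauchly_gg(wide: pd.DataFrame, groups: pd.Series) -> tuple[float, float, float]:
    """Mauchly W, its p, and Greenhouse–Geisser ε from the pooled
    within-group covariance of the repeated measures."""
    k = wide.shape[1]
    glabels = groups.unique()
    n_total = wide.shape[0]
    d = n_total - glabels.size  # error df of the pooled covariance
    pooled = np.zeros((k, k))
    for g in glabels:
        sub = wide.loc[groups == g].to_numpy()
        pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
    pooled /= d
    C = _orthonormal_contrasts(k)
    S = C @ pooled @ C.T
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 0.0, None)
    # Greenhouse–Geisser ε from the contrast-covariance eigenvalues
    gg_eps = float(eig.sum() ** 2 / ((k - 1) * (eig**2).sum()))
    gg_eps = min(max(gg_eps, 1.0 / (k - 1)), 1.0)
    # Mauchly's W with the standard chi-square approximation
    detS = float(np.linalg.det(S))
    trS = float(np.trace(S))
    if detS <= 0 or trS <= 0:
        return 0.0, 0.0, gg_eps
    W = detS / (trS / (k - 1)) ** (k - 1)
    q = k - 1
    f = 1.0 - (2.0 * q * q + q + 2.0) / (6.0 * q * d)
    chi2 = -d * f * math.log(W)
    df = q * (q + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(W), p, gg_eps


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    alpha_sphericity: float = 0.05,
) -> AnovaResult:
    """Univariate mixed ANOVA: one between factor × one within factor.

    Requires a complete design (every subject observed at every within
    level, exactly once); group sizes may differ.  The SS decomposition
    splits the between-subject stratum into the group effect and the
    subject-within-group error, and the within-subject stratum into the
    session effect, the group × session interaction, and the session ×
    subject error (sequential projections, which coincide with the
    classical balanced-design formulas when group sizes are equal).

    For k ≥ 3 within levels Mauchly's W tests sphericity on the pooled
    within-group covariance; Greenhouse–Geisser ε rescales both degrees
    of freedom of the within-subject F tests.  ``p_headline`` is the GG
    p whenever Mauchly is significant at ``alpha_sphericity``, else the
    uncorrected p (both are always reported).  η²G divides each effect
    SS by effect SS + subject error SS + within error SS.
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing observations: incomplete designs are not supported")
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="count")
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError(
            "incomplete design: every subject must be observed exactly once "
            "at every within level"
        )
    groups_per_subj = df.groupby(subject)[between].nunique()
    if (groups_per_subj != 1).any():
        raise ValueError("each subject must belong to exactly one group")

    wide = df.pivot(index=subject, columns=within, values=dv)
    subj_group = df.groupby(subject)[between].first().loc[wide.index]
    glabels = list(pd.unique(subj_group))
    n_g = subj_group.value_counts().to_dict()
    if min(n_g.values()) < 2:
        raise ValueError("each group needs at least two subjects")
    N = wide.shape[0]
    k = wide.shape[1]
    G = len(glabels)
    y = wide.to_numpy()

    grand = y.mean()
    subj_means = y.mean(axis=1)
    sess_means = y.mean(axis=0)  # subject-weighted
    group_means = {g: subj_means[(subj_group == g).to_numpy()].mean() for g in glabels}
    cell_means = wide.groupby(subj_group).mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(k * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in glabels))
    ss_subj = ss_between_subj - ss_group
    ss_session = float(N * ((sess_means - grand) ** 2).sum())
    ss_cells_within = float(
        sum(
            n_g[g] * ((cell_means.loc[g].to_numpy() - group_means[g]) ** 2).sum()
            for g in glabels
        )
    )
    ss_inter = ss_cells_within - ss_session
    ss_err_within = ss_total - ss_between_subj - ss_session - ss_inter

    df_group, df_subj = G - 1, N - G
    df_sess, df_inter = k - 1, (G - 1) * (k - 1)
    df_err = (N - G) * (k - 1)

    ms_subj = ss_subj / df_subj
    ms_err = ss_err_within / df_err if df_err > 0 else float("nan")

    if k >= 3:
        mauchly_w, mauchly_p, gg_eps = _mauchly_gg(wide, subj_group)
    else:
        mauchly_w, mauchly_p, gg_eps = 1.0, 1.0, 1.0
    sphericity_violated = k >= 3 and mauchly_p < alpha_sphericity

    eta_denom_err = ss_subj + ss_err_within

    def _row(effect, ss, df1, df2, ms_error, within_effect):
        # a zero error stratum (noiseless data) gives an infinite F
        F = (ss / df1) / ms_error if ms_error > 0 else float("inf")
        p_unc = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        if within_effect and gg_eps < 1.0:
            p_gg = float(sps.f.sf(F, gg_eps * df1, gg_eps * df2))
        else:
            p_gg = p_unc
        return {
            "effect": effect,
            "ss": ss,
            "df1": df1,
            "df2": df2,
            "ms": ss / df1,
            "f": F,
            "p_unc": p_unc,
            "mauchly_w": mauchly_w if within_effect else float("nan"),
            "mauchly_p": mauchly_p if within_effect else float("nan"),
            "gg_eps": gg_eps if within_effect else float("nan"),
            "df1_gg": gg_eps * df1 if within_effect else df1,
            "df2_gg": gg_eps * df2 if within_effect else df2,
            "p_gg": p_gg,
            "p_headline": p_gg if (within_effect and sphericity_violated) else p_unc,
            "eta2_g": ss / (ss + eta_denom_err),
        }

    table = pd.DataFrame(
        [
            _row(between, ss_group, df_group, df_subj, ms_subj, False),
            _row(within, ss_session, df_sess, df_err, ms_err, True),
            _row(f"{between}:{within}", ss_inter, df_inter, df_err, ms_err, True),
        ]
    )
    return AnovaResult(
        table=table,
        ss_subject=ss_subj,
        ss_error_within=ss_err_within,
        ss_total=ss_total,
        cell_means=cell_means,
        n_per_group={str(g): int(n_g[g]) for g in glabels},
    )


def tukey_hsd(
    cell_means: Sequence[float],
    error_ms: float,
    df_error: float,
    n_per_cell: int,
) -> np.ndarray:
    """Tukey HSD adjusted p values for all pairs of fitted cell means.

    q_ij = |m_i − m_j| / √(MS_error / n); p from the studentized range
    distribution with ``len(cell_means)`` groups and ``df_error`` df.
    Returns a symmetric matrix of adjusted p values (diagonal = 1).
    """
    means = np.asarray(cell_means, dtype=float)
    if error_ms <= 0:
        raise ValueError("error mean square must be positive")
    if n_per_cell < 1 or df_error <= 0:
        raise ValueError("n_per_cell and df_error must be positive")
    kk = means.size
    se = math.sqrt(error_ms / n_per_cell)
    p = np.ones((kk, kk))
    for i in range(kk):
        for j in range(i + 1, kk):
            q = abs(means[i] - means[j]) / se
            pij = float(studentized_range.sf(q, kk, df_error))
            p[i, j] = p[j, i] = min(1.0, pij)
    return p


# ---------------------------------------------------------------------------
# Minimization randomization


@dataclass
class AssignmentState:
    """Current rosters for covariate-adaptive minimization.

    Covariates carried for balance: age (years), sex ("F"/"M"), Barthel
    index, and 9HPT PRE time (s) — numeric covariates are balanced on
    |group-mean difference| / pooled SD, sex on the absolute difference
    in female proportion.
    """

    rosters: Dict[str, list] = field(default_factory=lambda: {"together": [], "in_turn": []})

    NUMERIC = ("age", "barthel_pre", "pegboard_pre_s")

    @property
    def sizes(self) -> Dict[str, int]:
        return {g: len(r) for g, r in self.rosters.items()}

    def add(self, group: str, record) -> None:
        self.rosters[group].append(record)

    def imbalance(self, extra: Optional[Mapping[str, list]] = None) -> float:
        """Standardized covariate imbalance of the current (or extended)
        rosters; +inf while either group is empty."""
        rosters = {g: list(r) for g, r in self.rosters.items()}
        if extra:
            for g, recs in extra.items():
                rosters[g] = rosters[g] + list(recs)
        ga, gb = rosters["together"], rosters["in_turn"]
        if not ga or not gb:
            return float("inf")
        everyone = ga + gb
        total = 0.0
        for cov in self.NUMERIC:
            va = np.array([getattr(r, cov) for r in ga], dtype=float)
            vb = np.array([getattr(r, cov) for r in gb], dtype=float)
            vall = np.array([getattr(r, cov) for r in everyone], dtype=float)
            sd = vall.std(ddof=1) if vall.size > 1 else 0.0
            scale = sd if sd > 0 else 1.0
            total += abs(va.mean() - vb.mean()) / scale
        fa = np.mean([1.0 if r.sex == "F" else 0.0 for r in ga])
        fb = np.mean([1.0 if r.sex == "F" else 0.0 for r in gb])
        total += abs(fa - fb)
        return float(total)


def assign_minimized(
    candidates: Sequence,
    state: AssignmentState,
    seed: int,
) -> list[str]:
    """Quasi-randomly assign a small accrual batch to the two groups.

    Enumerates every labelling of the batch that keeps the group sizes
    within one of each other, scores each by the standardized covariate
    imbalance of the resulting rosters, and picks the minimum, breaking
    ties uniformly at random with ``seed``.  The chosen records are
    appended to ``state``.  Batches of 1–3 patients are supported.
    """
    if not 1 <= len(candidates) <= 3:
        raise ValueError("accrual batches must contain 1 to 3 patients")
    rng = np.random.default_rng(seed)
    sizes = state.sizes
    best_score = float("inf")
    best: list[tuple[str, ...]] = []
    for labels in product(("together", "in_turn"), repeat=len(candidates)):
        na = sizes["together"] + labels.count("together")
        nb = sizes["in_turn"] + labels.count("in_turn")
        if abs(na - nb) > 1:
            continue
        extra: Dict[str, list] = {"together": [], "in_turn": []}
        for lab, rec in zip(labels, candidates):
            extra[lab].append(rec)
        score = state.imbalance(extra)
        if score < best_score - 1e-12:
            best_score = score
            best = [labels]
        elif abs(score - best_score) <= 1e-12:
            best.append(labels)
    if not best:
        raise RuntimeError("no labelling satisfies the size constraint")
    chosen = best[int(rng.integers(len(best)))]
    for lab, rec in zip(chosen, candidates):
        state.add(lab, rec)
    return list(chosen)


# ---------------------------------------------------------------------------
# Transforms


def log_transform_outcomes(
    summary: pd.DataFrame, fields: Sequence[str]
) -> pd.DataFrame:
    """Natural-log transform of the named outcome columns.

    Positive-only: a non-positive value raises an error naming the
    offending record.  A ``transform`` provenance column records which
    fields were transformed.
    """
    out = summary.copy()
    for col in fields:
        vals = out[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~(vals > 0))
        if bad.size:
            raise ValueError(
                f"non-positive value in column {col!r} at row index "
                f"{out.index[bad[0]]!r}: {vals[bad[0]]}"
            )
        out[col] = np.log(vals)
    out["transform"] = f"log({','.join(fields)})"
    return out
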