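"""Mixed repeated-measures ANOVA with sphericity diagnostics.

The group comparison is a classical split-plot (mixed) design: one
between-subjects factor (group: elite vs dystonic) and one within-subjects
factor (harmonic, 11 levels), one observation per subject per harmonic
(the per-note mean edge position in pixels).

Sums of squares follow the classical univariate partition:

* between subjects: group (df g−1) tested against subjects-within-groups
  (df N−g);
* within subjects: harmonic (df k−1) and group×harmonic (df (g−1)(k−1)),
  both tested against the subject×harmonic error (df (N−g)(k−1)).

Sphericity of the within-subject covariance is assessed with Mauchly's W on
the pooled within-group covariance (per-group covariances averaged with df
weights, the standard choice when a between factor is present). When Mauchly
rejects at ``alpha``, the within-factor tests are reported with
Greenhouse–Geisser-corrected degrees of freedom (both corrected and
uncorrected p values are always computed). Huynh–Feldt is intentionally not
offered.

Observed (post-hoc) power uses the noncentral-F convention of mainstream
commercial statistics packages: noncentrality λ = F·df1, with
Greenhouse–Geisser-adjusted dfs whenever the corrected test is the one
reported. Other λ conventions exist; this one is deliberate and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "mixed_anova",
    "gg_epsilon",
    "mauchly_test",
    "estimated_marginal_means",
    "observed_power",
    "pooled_within_covariance",
]


@dataclass
class RmAnovaResult:
    """Full numeric output of the mixed repeated-measures analysis."""

    # sums of squares
    ss_group: float
    ss_subjects_within_group: float
    ss_harmonic: float
    ss_interaction: float
    ss_error_within: float
    ss_total: float
    # degrees of freedom
    df_group: int
    df_subjects_within_group: int
    df_harmonic: int
    df_interaction: int
    df_error_within: int
    # F statistics
    F_group: float
    F_harmonic: float
    F_interaction: float
    # sphericity diagnostics
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    gg_epsilon: float
    sphericity_violated: bool
    # p values
    p_group: float
    p_harmonic_uncorrected: float
    p_harmonic_gg: float
    p_interaction_uncorrected: float
    p_interaction_gg: float
    # summaries
    emm_group: dict = field(default_factory=dict)
    observed_power: dict = field(default_factory=dict)
    alpha: float = 0.05
    n_subjects: int = 0
    n_levels: int = 0

    @property
    def p_harmonic(self) -> float:
        """Reported p for the harmonic main effect (GG-corrected if violated)."""
        return self.p_harmonic_gg if self.sphericity_violated else self.p_harmonic_uncorrected

    @property
    def p_interaction(self) -> float:
        """Reported p for the group×harmonic interaction (GG if violated)."""
        return (
            self.p_interaction_gg
            if self.sphericity_violated
            else self.p_interaction_uncorrected
        )

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            out[k] = v
        out["p_harmonic"] = float(self.p_harmonic)
        out["p_interaction"] = float(self.p_interaction)
        return out

    def report(self) -> str:
        """Human-readable summary in the style of a results paragraph."""
        eps = self.gg_epsilon
        sph = (
            f"Mauchly's test indicated a violation of sphericity "
            f"(W = {self.mauchly_w:.3f}, p = {self.mauchly_p:.3g}); "
            f"Greenhouse-Geisser epsilon = {eps:.3f}."
            if self.sphericity_violated
            else f"Sphericity was not rejected (Mauchly W = {self.mauchly_w:.3f}, "
            f"p = {self.mauchly_p:.3g})."
        )
        corr = " after Greenhouse-Geisser adjustment of the degrees of freedom" \
            if self.sphericity_violated else ""
        emm = ", ".join(f"{g}: {m:.1f} px" for g, m in self.emm_group.items())
        lines = [
            sph,
            (
                f"Group main effect: F({self.df_group}, "
                f"{self.df_subjects_within_group}) = {self.F_group:.3f}, "
                f"p = {self.p_group:.3g}, observed power = "
                f"{self.observed_power['group']:.3f}."
            ),
            (
                f"Harmonic main effect: F({self.df_harmonic}, "
                f"{self.df_error_within}) = {self.F_harmonic:.3f}, "
                f"p = {self.p_harmonic:.3g}{corr}, observed power = "
                f"{self.observed_power['harmonic']:.3f}."
            ),
            (
                f"Group x harmonic interaction: F({self.df_interaction}, "
                f"{self.df_error_within}) = {self.F_interaction:.3f}, "
                f"p = {self.p_interaction:.3g}{corr}, observed power = "
                f"{self.observed_power['interaction']:.3f}."
            ),
            f"Estimated marginal means: {emm}.",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _wide_by_group(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Pivot the long table to one (n_subjects × k) matrix per group."""
    required = {"subject_id", "group", "harmonic", "value_px"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    wide = table.pivot_table(
        index=["group", "subject_id"], columns="harmonic", values="value_px"
    )
    if wide.isna().any().any():
        raise ValueError("missing cells: every subject needs one value per harmonic")
    counts = table.groupby(["subject_id", "harmonic"]).size()
    if (counts > 1).any():
        raise ValueError("duplicate (subject, harmonic) cells")
    out = {}
    for g in wide.index.get_level_values("group").unique():
        out[str(g)] = wide.loc[g].to_numpy(dtype=float)
    return out


def pooled_within_covariance(groups: dict[str, np.ndarray]) -> tuple[np.ndarray, int]:
    """Df-weighted average of per-group within-subject covariances.

    Returns ``(S, df)`` with ``df = N − g`` the pooled degrees of freedom.
    """
    k = next(iter(groups.values())).shape[1]
    acc = np.zeros((k, k))
    df = 0
    for mat in groups.values():
        n = mat.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects per group")
        acc += (n - 1) * np.cov(mat, rowvar=False)
        df += n - 1
    return acc / df, df


def gg_epsilon(within_cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from a k×k within-level covariance.

    ε̂ = trace(S̃)² / ((k−1)·ΣS̃²) with S̃ the double-centered covariance;
    equivalently k²·(mean diagonal)²/((k−1)·ΣΣ entries²). Clipped to
    [1/(k−1), 1]; equals 1 exactly under compound symmetry.
    """
    s = np.asarray(within_cov, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(s, s.T, atol=1e-8 * max(1.0, np.abs(s).max())):
        raise ValueError("covariance must be symmetric")
    k = s.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within levels")
    row = s.mean(axis=0, keepdims=True)
    centered = s - row - row.T + s.mean()
    num = np.trace(centered) ** 2
    den = (k - 1) * np.sum(centered**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1)×k orthonormal rows, each orthogonal to the unit vector."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis[:, : k - 1])
    return q.T  # rows orthonormal, orthogonal to 1 by construction


def mauchly_test(
    within_cov: np.ndarray, n_subjects: int, n_groups: int = 1
) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test on a within-level covariance.

    ``n_subjects`` and ``n_groups`` determine the covariance degrees of
    freedom d = N − g (g = 1 for a single sample). Returns
    ``(W, chi2, df, p)``; a singular contrast-space covariance yields W = 0
    and p → 0 with a warning.
    """
    s = np.asarray(within_cov, dtype=float)
    k = s.shape[0]
    if k < 3:
        raise ValueError("Mauchly's test requires at least 3 within levels")
    c = _orthonormal_contrasts(k)
    t = c @ s @ c.T
    p_dim = k - 1
    df = k * (k - 1) // 2 - 1
    eig = np.linalg.eigvalsh(t)
    mean_eig = np.trace(t) / p_dim
    if np.any(eig <= 1e-12 * max(mean_eig, 1e-300)) or mean_eig <= 0:
        warnings.warn("singular contrast covariance: Mauchly W = 0", stacklevel=2)
        return 0.0, float("inf"), df, 0.0
    w = float(np.prod(eig / mean_eig))
    d = n_subjects - n_groups
    if d < 1:
        raise ValueError("covariance degrees of freedom must be positive")
    rho = 1.0 - (2.0 * p_dim**2 + p_dim + 2.0) / (6.0 * p_dim * d)
    chi2 = -rho * d * np.log(w)
    p = float(sps.chi2.sf(chi2, df))
    return w, float(chi2), df, p


def estimated_marginal_means(table: pd.DataFrame) -> dict[str, float]:
    """Per-group EMMs: unweighted mean over harmonics of per-harmonic group means.

    With complete data this equals each group's grand cell mean.
    """
    groups = _wide_by_group(table)
    return {g: float(mat.mean()) for g, mat in groups.items()}


def observed_power(
    f_obs: float, df1: float, df2: float, alpha: float = 0.05
) -> float:
    """Post-hoc power at the observed effect size.

    λ = F·df1; power = P(F'(df1, df2, λ) > F_crit) with F_crit the central
    upper-α quantile. At F = 0 this equals α; it increases monotonically in F.
    """
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if f_obs < 0:
        raise ValueError("F must be non-negative")
    if not np.isfinite(f_obs):
        return 1.0
    fcrit = sps.f.isf(alpha, df1, df2)
    lam = f_obs * df1
    if lam == 0:
        return float(alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def rm_anova_single(values: np.ndarray) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA for a single group.

    ``values`` is (n_subjects × k). Returns ``(F, df1, df2, p)`` for the
    within-factor effect; with k = 2 the F statistic equals the squared
    paired t statistic on the level difference.
    """
    y = np.asarray(values, dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    grand = y.mean()
    ss_level = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_level - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    f = (ss_level / df1) / (ss_err / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# the mixed ANOVA
# ---------------------------------------------------------------------------

def mixed_anova(table: pd.DataFrame, alpha: float = 0.05) -> RmAnovaResult:
    """Two-factor mixed ANOVA (between: group, within: harmonic).

    ``table`` is long-format with columns ``subject_id, group, harmonic,
    value_px`` and a complete within-factor per subject (missing cells are an
    error, never silently dropped). Returns the full partition, sphericity
    diagnostics, GG-corrected and uncorrected p values, per-group estimated
    marginal means and observed power for each test.
    """
    groups = _wide_by_group(table)
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(groups)}")
    labels = sorted(groups)
    mats = [groups[g] for g in labels]
    k = mats[0].shape[1]
    if mats[0].shape[1] != mats[1].shape[1]:
        raise ValueError("groups disagree on within-factor levels")
    ns = [m.shape[0] for m in mats]
    n_total = sum(ns)
    g = len(mats)
    all_vals = np.vstack(mats)

    grand = all_vals.mean()
    ss_total = float(((all_vals - grand) ** 2).sum())

    subj_means = all_vals.mean(axis=1)
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    group_means = np.array([m.mean() for m in mats])
    ss_group = float(k * sum(n * (gm - grand) ** 2 for n, gm in zip(ns, group_means)))
    ss_subj_within = ss_between_subj - ss_group

    level_means = all_vals.mean(axis=0)  # weighted across groups
    ss_harmonic = float(n_total * ((level_means - grand) ** 2).sum())

    cell_means = [m.mean(axis=0) for m in mats]
    ss_cells = float(
        sum(n * ((cm - grand) ** 2).sum() for n, cm in zip(ns, cell_means))
    )
    ss_interaction = ss_cells - ss_harmonic - ss_group
    ss_error_within = ss_total - ss_between_subj - ss_harmonic - ss_interaction

    df_group = g - 1
    df_subj_within = n_total - g
    df_harmonic = k - 1
    df_interaction = (g - 1) * (k - 1)
    df_error_within = (n_total - g) * (k - 1)

    # rounding in the SS partition can leave degenerate error terms slightly
    # negative; anything below this scale counts as zero variance
    zero_scale = 1e-12 * max(ss_total / max(n_total * k - 1, 1), 1e-30)

    def _ratio(ss_num, df_num, ss_den, df_den):
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den
        if ms_den <= zero_scale:
            if ms_num <= zero_scale:
                return 0.0
            warnings.warn("zero error variance: F reported as inf", stacklevel=3)
            return float("inf")
        # SS are non-negative up to rounding; clamp the residue
        return float(max(ms_num, 0.0) / ms_den)

    f_group = _ratio(ss_group, df_group, ss_subj_within, df_subj_within)
    f_harm = _ratio(ss_harmonic, df_harmonic, ss_error_within, df_error_within)
    f_inter = _ratio(ss_interaction, df_interaction, ss_error_within, df_error_within)

    p_group = float(sps.f.sf(f_group, df_group, df_subj_within))
    p_harm_unc = float(sps.f.sf(f_harm, df_harmonic, df_error_within))
    p_inter_unc = float(sps.f.sf(f_inter, df_interaction, df_error_within))

    # sphericity on the pooled within-group covariance
    pooled, _ = pooled_within_covariance(groups)
    eps = gg_epsilon(pooled)
    if k >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, chi2, mdf, mp = mauchly_test(pooled, n_total, n_groups=g)
    else:
        w, chi2, mdf, mp = 1.0, 0.0, 0, 1.0
    violated = mp < alpha

    p_harm_gg = float(sps.f.sf(f_harm, df_harmonic * eps, df_error_within * eps))
    p_inter_gg = float(sps.f.sf(f_inter, df_interaction * eps, df_error_within * eps))

    # observed power, on the dfs of the reported tests
    if violated:
        df_h = (df_harmonic * eps, df_error_within * eps)
        df_i = (df_interaction * eps, df_error_within * eps)
    else:
        df_h = (df_harmonic, df_error_within)
        df_i = (df_interaction, df_error_within)
    power = {
        "group": observed_power(f_group, df_group, df_subj_within, alpha),
        "harmonic": observed_power(f_harm, *df_h, alpha),
        "interaction": observed_power(f_inter, *df_i, alpha),
    }

    emm = {lab: float(m.mean()) for lab, m in zip(labels, mats)}

    return RmAnovaResult(
        ss_group=ss_group,
        ss_subjects_within_group=ss_subj_within,
        ss_harmonic=ss_harmonic,
        ss_interaction=ss_interaction,
        ss_error_within=ss_error_within,
        ss_total=ss_total,
        df_group=df_group,
        df_subjects_within_group=df_subj_within,
        df_harmonic=df_harmonic,
        df_interaction=df_interaction,
        df_error_within=df_error_within,
        F_group=f_group,
        F_harmonic=f_harm,
        F_interaction=f_inter,
        mauchly_w=w,
        mauchly_chi2=chi2,
        mauchly_df=mdf,
        mauchly_p=mp,
        gg_epsilon=eps,
        sphericity_violated=bool(violated),
        p_group=p_group,
        p_harmonic_uncorrected=p_harm_unc,
        p_harmonic_gg=p_harm_gg,
        p_interaction_uncorrected=p_inter_unc,
        p_interaction_gg=p_inter_gg,
        emm_group=emm,
        observed_power=power,
        alpha=alpha,
        n_subjects=n_total,
        n_levels=k,
    )
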