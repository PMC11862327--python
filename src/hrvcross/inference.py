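"""Crossover inference: baseline correction, paired net effects, bootstrap,
multiplicity adjustment, effect sizes, Bayes factors, and multivariate tests.

The analysis follows the standard within-subject contrast logic for a
2 (condition) x 2 (side) crossover with a no-stimulation baseline phase:

1. every index is baseline-corrected within session
   (delta = phase value − same-session baseline value),
2. the net stimulation effect is the pairwise difference
   delta(active) − delta(sham) per subject, side, and phase,
3. the mean net effect b is tested with a studentized bootstrap of the mean
   (two-tailed resampling p with a 1/B floor; a raw percentile variant is
   available), adjusted across tests with Benjamini–Hochberg, and
   complemented by Cohen's dz and a JZS Bayes factor with a Cauchy(0, 0.5)
   prior on the standardized effect.

For main effects across sides, each subject's two side estimates are
averaged first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BootstrapConfig",
    "EffectEstimate",
    "ManovaResult",
    "baseline_correct",
    "net_effect",
    "bootstrap_effect",
    "bh_adjust",
    "cohens_dz",
    "jzs_bayes_factor",
    "manova_pillai",
    "side_correlation_test",
    "side_consistency_test",
    "analyze_study",
]

INDICES = ("hr", "sdrr", "rmssd", "hf", "lfhf", "resp_cpm")
HRV_DVS = ("sdrr", "rmssd", "hf", "lfhf")
MIN_SUBJECTS = 5


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings: B resamples, two-tailed level alpha, RNG seed."""

    n_resamples: int = 50_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1000:
            raise ValueError("n_resamples must be >= 1000")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class EffectEstimate:
    """Bootstrap summary of one contrast.

    ``b`` is the sample mean difference; ``ci_lo``/``ci_hi`` the percentile
    bootstrap bounds at level 1−alpha; ``p_boot`` the two-tailed resampling
    p; ``p_adj`` is filled by :func:`bh_adjust` downstream; ``dz`` and
    ``bf10`` are None when not requested.
    """

    b: float
    ci_lo: float
    ci_hi: float
    p_boot: float
    n: int
    p_adj: float | None = None
    dz: float | None = None
    bf10: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.b <= self.ci_hi):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class ManovaResult:
    pillai_v: float
    f_stat: float
    df1: float
    df2: float
    p_value: float


# ---------------------------------------------------------------------------
# table manipulation

def baseline_correct(summary: pd.DataFrame, indices=INDICES) -> pd.DataFrame:
    """Subtract each session's baseline row from its later-phase rows.

    Expects a tidy table with columns subject, session, condition, side,
    phase plus the index columns; returns the delta table for the
    non-baseline phases. Sessions without a baseline phase are dropped (and
    listed in ``df.attrs['excluded_sessions']``).
    """
    keys = ["subject", "session", "condition", "side"]
    out, excluded = [], []
    for key, grp in summary.groupby(keys, sort=True):
        base = grp[grp["phase"] == "baseline"]
        if base.empty:
            excluded.append(key)
            continue
        base = base.iloc[0]
        for _, row in grp[grp["phase"] != "baseline"].iterrows():
            rec = dict(zip(keys, key))
            rec["phase"] = row["phase"]
            for ix in indices:
                if ix in summary.columns:
                    rec[ix] = row[ix] - base[ix] if pd.notna(row[ix]) and pd.notna(base[ix]) else np.nan
            out.append(rec)
    deltas = pd.DataFrame(out)
    deltas.attrs["excluded_sessions"] = excluded
    return deltas


def net_effect(deltas: pd.DataFrame, active: str = "taVNS", reference: str = "sham",
               indices=INDICES) -> pd.DataFrame:
    """Pairwise difference delta(active) − delta(reference) per
    subject x side x phase. Unmatched pairs are dropped and listed in
    ``df.attrs['unmatched']``."""
    cols = [ix for ix in indices if ix in deltas.columns]
    a = deltas[deltas["condition"] == active]
    r = deltas[deltas["condition"] == reference]
    merged = a.merge(
        r, on=["subject", "side", "phase"], suffixes=("_a", "_r"), how="outer",
        indicator=True,
    )
    unmatched = merged[merged["_merge"] != "both"][["subject", "side", "phase"]]
    both = merged[merged["_merge"] == "both"]
    out = both[["subject", "side", "phase"]].copy()
    for ix in cols:
        out[ix] = both[f"{ix}_a"].to_numpy() - both[f"{ix}_r"].to_numpy()
    out.attrs["unmatched"] = unmatched.to_records(index=False).tolist()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# univariate machinery

def bootstrap_effect(diffs, cfg: BootstrapConfig | None = None,
                     method: str = "studentized") -> EffectEstimate:
    """Bootstrap of the mean of paired differences.

    ``method="studentized"`` (default) resamples the t-pivot
    t* = (mean* − b)/se*; the CI is b − se·[q_hi, q_lo](t*) and
    p = 2·min(P(t* ≤ t0), P(t* ≥ t0)) with t0 = b/se. The pivot corrects the
    finite-sample anticonservatism of the raw percentile test while keeping
    the resampling nonparametric.

    ``method="percentile"`` uses the raw resampled means: CI from the
    [α/2, 1−α/2] percentiles and p = 2·min(P(mean* ≤ 0), P(mean* ≥ 0)).

    Either way p is clipped to [1/n_resamples, 1]. Identical diffs yield the
    degenerate CI [b, b] with p at the floor (or 1 when b = 0).
    """
    cfg = cfg or BootstrapConfig()
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    n = diffs.size
    if n < MIN_SUBJECTS:
        raise ValueError(f"need at least {MIN_SUBJECTS} paired differences, got {n}")
    if method not in ("studentized", "percentile"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    b = float(diffs.mean())
    sd = diffs.std(ddof=1)
    p_floor = 1.0 / cfg.n_resamples
    if sd == 0:  # degenerate: all differences identical
        return EffectEstimate(b=b, ci_lo=b, ci_hi=b,
                              p_boot=1.0 if b == 0 else p_floor, n=n)

    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n, size=(cfg.n_resamples, n))
    samp = diffs[idx]
    means = samp.mean(axis=1)
    if method == "percentile":
        lo, hi = np.percentile(means, [100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)])
        p = 2.0 * min((means <= 0).mean(), (means >= 0).mean())
    else:
        se = sd / math.sqrt(n)
        se_star = samp.std(axis=1, ddof=1) / math.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = np.where(
                se_star > 0, (means - b) / se_star,
                np.where(means == b, 0.0, np.sign(means - b) * np.inf),
            )
        # zero-variance resamples (possible with heavily tied data) give an
        # infinite pivot; cap it at a magnitude beyond any meaningful quantile
        # so percentile interpolation stays finite
        t_star = np.clip(t_star, -100.0, 100.0)
        q_lo, q_hi = np.percentile(t_star, [100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)])
        lo, hi = b - q_hi * se, b - q_lo * se
        t0 = b / se
        p = 2.0 * min((t_star <= t0).mean(), (t_star >= t0).mean())
    p = float(min(max(p, p_floor), 1.0))
    return EffectEstimate(b=b, ci_lo=float(min(lo, b)), ci_hi=float(max(hi, b)),
                          p_boot=p, n=n)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def cohens_dz(diffs) -> float:
    """Within-subject effect size: mean of differences over their sample SD."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 2:
        raise ValueError("need at least two differences")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; dz undefined")
    return float(diffs.mean() / sd)


def jzs_bayes_factor(diffs=None, cauchy_scale: float = 0.5,
                     t: float | None = None, n: int | None = None) -> float:
    """JZS Bayes factor BF10 of a one-sample t-test.

    The alternative places a Cauchy(0, ``cauchy_scale``) prior on the
    standardized effect delta; BF10 is the ratio of the marginal likelihood
    of the observed t under that prior to the central-t null likelihood.
    The prior integral is evaluated with adaptive quadrature under the
    substitution delta = r·tan(theta), which maps the Cauchy measure to the
    uniform measure on (−π/2, π/2).

    Either ``diffs`` or the pair ``(t, n)`` must be given.
    """
    if t is None or n is None:
        d = np.asarray(diffs, dtype=float)
        d = d[np.isfinite(d)]
        n = d.size
        if n < 2:
            raise ValueError("need at least two differences")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance; t statistic undefined")
        t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    root_n = math.sqrt(n)
    r = cauchy_scale

    def integrand(theta: float) -> float:
        delta = r * math.tan(theta)
        return stats.nct.pdf(t, df, delta * root_n) / math.pi

    alt, err = integrate.quad(integrand, -math.pi / 2, math.pi / 2,
                              limit=200, epsabs=1e-12, epsrel=1e-10)
    null = stats.t.pdf(t, df)
    if null <= 0 or not np.isfinite(alt) or alt <= 0 or err > max(1e-8, 1e-4 * alt):
        raise ArithmeticError(
            f"Bayes factor integration failed (alt={alt}, err={err}, null={null})"
        )
    return float(alt / null)


# ---------------------------------------------------------------------------
# multivariate test

def manova_pillai(dv_matrix, design, test_cols) -> ManovaResult:
    """Pillai's trace for a set of design columns in a multivariate GLM.

    ``dv_matrix`` is n x p; ``design`` is the full n x k design matrix
    (including intercept); ``test_cols`` indexes the columns whose joint
    effect is tested. V = trace(H(H+E)^{-1}) with H/E the hypothesis and
    error SSCP matrices, and the standard Pillai F approximation
    F = ((2n̂+s+1)/(2m̂+s+1)) · V/(s−V) with df1 = s(2m̂+s+1),
    df2 = s(2n̂+s+1).
    """
    Y = np.asarray(dv_matrix, dtype=float)
    X = np.asarray(design, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n_obs, p = Y.shape
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix: an effect is aliased")
    if np.linalg.matrix_rank(Y - Y.mean(0)) < p:
        raise ValueError("DV matrix is rank-deficient (collinear columns)")

    test_cols = np.atleast_1d(test_cols).astype(int)
    q = test_cols.size
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid

    L = np.zeros((q, k))
    L[np.arange(q), test_cols] = 1.0
    LB = L @ B
    M = np.linalg.inv(L @ XtX_inv @ L.T)
    H = LB.T @ M @ LB

    eigvals = np.linalg.eigvals(np.linalg.solve(H + E, H))
    V = float(np.real(eigvals).sum())

    s = min(p, q)
    m_hat = (abs(p - q) - 1) / 2.0
    n_hat = (n_obs - k - p - 1) / 2.0
    df1 = s * (2 * m_hat + s + 1)
    df2 = s * (2 * n_hat + s + 1)
    if df2 <= 0:
        raise ValueError("not enough error degrees of freedom for the MANOVA")
    f_stat = (df2 / df1) * V / (s - V)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return ManovaResult(pillai_v=V, f_stat=float(f_stat), df1=df1, df2=df2,
                        p_value=p_value)


def manova_within(deltas: pd.DataFrame, dvs=HRV_DVS) -> dict:
    """Pillai tests of the within-subject factors on the HRV delta vector.

    Observations are subject x side x phase baseline-corrected values per
    condition; factors (stimulation, side, phase, stimulation x phase) enter
    as effect-coded columns. Returns a dict of ManovaResult keyed by factor.
    """
    work = deltas.dropna(subset=[d for d in dvs if d in deltas.columns])
    Y = work[list(dvs)].to_numpy(dtype=float)
    stim = np.where(work["condition"] == "taVNS", 1.0, -1.0) if "condition" in work else None
    side = np.where(work["side"] == "right", 1.0, -1.0)
    phase = np.where(work["phase"] == "caloric_load", 1.0, -1.0)
    cols = {"intercept": np.ones(len(work)), "side": side, "phase": phase}
    if stim is not None:
        cols["stimulation"] = stim
        cols["stim_x_phase"] = stim * phase
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    out = {}
    for name in names[1:]:
        out[name] = manova_pillai(Y, X, [names.index(name)])
    return out


def side_correlation_test(r_active, r_reference):
    """Fisher-z comparison of cross-side correlations.

    For each cardiovascular index, ``r_active``/``r_reference`` hold the
    correlation (across subjects) between left- and right-side induced
    changes under the active and reference conditions. The paired
    z-transformed differences are tested against zero with a one-sample
    t-test. Returns ``(t, df, p)``.
    """
    ra = np.asarray(r_active, dtype=float)
    rr = np.asarray(r_reference, dtype=float)
    if ra.shape != rr.shape:
        raise ValueError("correlation vectors must have equal length")
    if np.any(np.abs(ra) >= 1) or np.any(np.abs(rr) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher z transform")
    dz_ = np.arctanh(ra) - np.arctanh(rr)
    if np.allclose(dz_, 0):
        return 0.0, len(dz_) - 1, 1.0
    res = stats.ttest_1samp(dz_, 0.0)
    return float(res.statistic), len(dz_) - 1, float(res.pvalue)


def side_consistency_test(deltas: pd.DataFrame, indices=INDICES,
                          active: str = "taVNS", reference: str = "sham") -> dict:
    """Are induced changes more consistent across sides under the active
    condition?

    For every index × phase, correlates (across subjects) the left- and
    right-side baseline-corrected changes, separately per condition, then
    compares the two correlation vectors with :func:`side_correlation_test`.
    Returns ``{"r_active", "r_reference", "labels", "t", "df", "p"}``.
    """
    cols = [ix for ix in indices if ix in deltas.columns]
    r_a, r_r, labels = [], [], []
    for phase in sorted(deltas["phase"].unique()):
        sub = deltas[deltas["phase"] == phase]
        for ix in cols:
            rs = {}
            for cond in (active, reference):
                wide = (
                    sub[sub["condition"] == cond]
                    .pivot_table(index="subject", columns="side", values=ix)
                    .dropna()
                )
                if len(wide) < 3 or {"left", "right"} - set(wide.columns):
                    rs = None
                    break
                rs[cond] = float(np.corrcoef(wide["left"], wide["right"])[0, 1])
            if rs is None or any(abs(v) >= 1 for v in rs.values()):
                continue
            r_a.append(rs[active])
            r_r.append(rs[reference])
            labels.append((ix, phase))
    if not labels:
        raise ValueError("no index/phase with enough complete left/right pairs")
    t, df, p = side_correlation_test(r_a, r_r)
    return {"r_active": np.asarray(r_a), "r_reference": np.asarray(r_r),
            "labels": labels, "t": t, "df": df, "p": p}


# ---------------------------------------------------------------------------
# study-level driver

def _effects_block(net: pd.DataFrame, index: str, phase: str,
                   cfg: BootstrapConfig, seed_offset: int) -> dict:
    """Both-sides (side-averaged), left, and right estimates for one index/phase."""
    sub = net[net["phase"] == phase][["subject", "side", index]].dropna()
    per_side = {
        side: sub[sub["side"] == side].set_index("subject")[index]
        for side in ("left", "right")
    }
    both = sub.groupby("subject")[index].mean()
    out = {}
    for li, (label, series) in enumerate((("both", both), ("left", per_side["left"]),
                                          ("right", per_side["right"]))):
        d = series.to_numpy(dtype=float)
        if label != "both" and d.size < MIN_SUBJECTS:
            continue  # a side with too few matched sessions is not reported
        est = bootstrap_effect(
            d, BootstrapConfig(cfg.n_resamples, cfg.alpha,
                               seed=cfg.seed + seed_offset + li)
        )
        if label == "both":
            est.dz = cohens_dz(d) if d.std(ddof=1) > 0 else None
            est.bf10 = jzs_bayes_factor(d) if d.std(ddof=1) > 0 else None
        out[label] = est
    return out


def analyze_study(summary: pd.DataFrame, cfg: BootstrapConfig | None = None,
                  indices=INDICES) -> dict:
    """Full inference pass over a tidy per-phase summary table.

    Returns ``{"effects": DataFrame, "manova": dict, "deltas": DataFrame,
    "net": DataFrame}``. The effects table mirrors the index x phase x side
    layout of a crossover report: b, CI, bootstrap p, BH-adjusted p (within
    each phase across indices), dz and BF10 for the side-averaged contrast.
    Refuses to run with fewer than 5 complete subjects.
    """
    cfg = cfg or BootstrapConfig()
    cols = [ix for ix in indices if ix in summary.columns]
    deltas = baseline_correct(summary, cols)
    net = net_effect(deltas, indices=cols)
    n_subj = net["subject"].nunique()
    if n_subj < MIN_SUBJECTS:
        raise ValueError(
            f"only {n_subj} subjects with matched taVNS/sham sessions; "
            f"inference needs at least {MIN_SUBJECTS}"
        )

    rows = []
    for pi, phase in enumerate(sorted(net["phase"].unique())):
        for ii, index in enumerate(cols):
            # indices unavailable for this dataset (e.g. spectral measures on
            # phases shorter than one analysis window) are skipped
            avail = net[net["phase"] == phase][["subject", index]].dropna()
            if avail.groupby("subject")[index].mean().size < MIN_SUBJECTS:
                continue
            blocks = _effects_block(net, index, phase, cfg, 1000 * pi + 10 * ii)
            for side, est in blocks.items():
                rows.append({
                    "index": index, "phase": phase, "side": side, "n": est.n,
                    "b": est.b, "ci_lo": est.ci_lo, "ci_hi": est.ci_hi,
                    "p_boot": est.p_boot, "dz": est.dz, "bf10": est.bf10,
                })
    effects = pd.DataFrame(rows)
    effects["p_adj"] = np.nan
    for phase in effects["phase"].unique():
        mask = (effects["phase"] == phase) & (effects["side"] == "both")
        effects.loc[mask, "p_adj"] = bh_adjust(effects.loc[mask, "p_boot"].to_numpy())

    manova = {}
    dvs = [d for d in HRV_DVS if d in deltas.columns]
    if len(dvs) >= 2 and deltas[dvs].dropna().shape[0] > len(dvs) + 6:
        try:
            manova = manova_within(deltas.dropna(subset=dvs), dvs)
        except ValueError:
            manova = {}
    return {"effects": effects, "manova": manova, "deltas": deltas, "net": net}
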