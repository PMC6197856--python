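"""Laminar discrimination statistics.

The core contrast: for a given frequency band and window of interest, the
unsigned fractional change in power from baseline, |P_WOI − P_base| / P_base,
is computed per trial on every vertex of both surfaces; an ROI is defined
from the trial-mean maps (top 20% of either surface, expanded to full
white/pial pairs); per-trial ROI means are compared between surfaces with a
paired t-test whose noise variance is floored to attenuate artifactually
high t-values.  A positive t classifies the signal as superficial (pial),
negative as deep (white matter).  Group inference uses the exact Wilcoxon
signed-rank test on per-participant pial−white differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .forward import geodesic_distances
from .mesh import LaminarModel
from .spectral import SignalDefinition
from .stats import WilcoxonResult, friedman_test, wilcoxon_exact

__all__ = [
    "LaminarResult",
    "GroupResult",
    "fractional_change",
    "define_roi",
    "laminar_ttest",
    "vertexwise_t",
    "group_wilcoxon",
    "condition_compare",
    "leadfield_bias_analysis",
]


@dataclass
class LaminarResult:
    """Single-participant laminar classification for one signal."""

    signal: SignalDefinition | None
    roi: np.ndarray  # pair indices
    pial_trials: np.ndarray  # per-trial ROI mean, pial surface
    white_trials: np.ndarray
    t: float
    p: float
    classification: str  # 'superficial' | 'deep'
    roi_metric: str = "global"
    vertexwise: np.ndarray | None = None

    @property
    def difference(self) -> float:
        """Trial-mean pial − white ROI value (the group-test quantity)."""
        return float(self.pial_trials.mean() - self.white_trials.mean())


@dataclass
class GroupResult:
    differences: np.ndarray  # per participant, pial − white
    wilcoxon: WilcoxonResult
    n_superficial: int
    n_deep: int
    null_value: float = 0.0


def fractional_change(power_woi: np.ndarray, power_baseline: np.ndarray) -> np.ndarray:
    """Unsigned fractional change in power, |P_WOI − P_base| / P_base.

    Decreases count the same as increases; the result is ≥ 0.
    """
    w = np.asarray(power_woi, float)
    b = np.asarray(power_baseline, float)
    if np.any(b <= 0):
        raise ValueError("baseline power must be strictly positive")
    return np.abs(w - b) / b


def _top_fraction_threshold(values: np.ndarray, percentile: float) -> float:
    """Order-statistic threshold: the m-th largest value where m is the
    nominal size of the top (100−percentile)% set.  Using an order statistic
    (rather than an interpolated percentile) makes the ROI invariant to
    monotone rescaling of the maps."""
    n = len(values)
    m = max(1, int(np.floor(n * (100.0 - percentile) / 100.0)))
    return float(np.sort(values)[::-1][m - 1])


def define_roi(
    pial_map: np.ndarray,
    white_map: np.ndarray,
    percentile: float = 80.0,
    metric: str = "global",
    mask: np.ndarray | None = None,
    model: LaminarModel | None = None,
    radius: float = 0.010,
) -> np.ndarray:
    """Vertex-pair ROI from trial-mean unsigned fractional change maps.

    Vertices on either surface at or above the ``percentile`` threshold of
    that surface's map (ties included), together with their partners on the
    other surface, form the ROI.  ``metric='functional'`` restricts the
    threshold computation to a geodesic neighborhood (``radius`` m on the
    pial mesh) of the peak vertex; ``metric='anatomical'`` restricts it to a
    boolean ``mask`` of pairs.  The maps must come from a contrast that is
    orthogonal to the laminar (pial vs white) comparison — i.e. trial means,
    not surface differences.
    """
    pial_map = np.asarray(pial_map, float)
    white_map = np.asarray(white_map, float)
    if pial_map.shape != white_map.shape:
        raise ValueError("surface maps must have equal length")
    n = len(pial_map)
    if metric == "global":
        candidates = np.arange(n)
    elif metric == "functional":
        if model is None:
            raise ValueError("functional ROI requires the laminar model")
        peak = int(np.argmax(np.maximum(pial_map, white_map)))
        d = geodesic_distances(model.pial, np.array([peak]), cutoff=radius * 2)[0]
        candidates = np.where(d <= radius)[0]
    elif metric == "anatomical":
        if mask is None:
            raise ValueError("anatomical ROI requires a mask")
        candidates = np.where(np.asarray(mask, bool))[0]
    else:
        raise ValueError(f"unknown ROI metric: {metric}")
    if candidates.size == 0:
        raise ValueError("no candidate vertices for ROI")
    sel = np.zeros(n, dtype=bool)
    for surf_map in (pial_map, white_map):
        thr = _top_fraction_threshold(surf_map[candidates], percentile)
        sel[candidates[surf_map[candidates] >= thr]] = True
    roi = np.where(sel)[0]
    if roi.size == 0:
        raise ValueError("empty ROI")
    return roi


def laminar_ttest(
    pial_trials: np.ndarray,
    white_trials: np.ndarray,
    variance_floor: float | None = None,
    use_floor: bool = True,
) -> tuple[float, float, str]:
    """Paired t-test of pial vs white per-trial ROI means with a corrected
    (floored) noise variance.

    The paired-difference variance is floored at ``variance_floor`` (default
    1% of the squared mean difference) so that near-zero-variance data
    cannot produce artifactually high t-values.  Returns (t, p,
    classification) with classification 'superficial' iff t > 0.
    """
    p_tr = np.asarray(pial_trials, float)
    w_tr = np.asarray(white_trials, float)
    if p_tr.shape != w_tr.shape:
        raise ValueError("trial vectors must have equal length")
    n = len(p_tr)
    if n < 2:
        raise ValueError("need at least 2 trials")
    d = p_tr - w_tr
    md = d.mean()
    var = d.var(ddof=1)
    if use_floor:
        floor = 0.01 * md**2 if variance_floor is None else variance_floor
        var = max(var, floor)
    if var == 0:
        t = 0.0
    else:
        t = md / np.sqrt(var / n)
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), ("superficial" if t > 0 else "deep")


def vertexwise_t(
    pial_power: np.ndarray,
    white_power: np.ndarray,
    roi: np.ndarray | None = None,
    use_floor: bool = True,
) -> np.ndarray:
    """Paired t per vertex pair (trials × pairs inputs), for the laminar
    t-distribution histograms."""
    P = np.atleast_2d(np.asarray(pial_power, float))
    W = np.atleast_2d(np.asarray(white_power, float))
    if roi is not None:
        P, W = P[:, roi], W[:, roi]
    out = np.empty(P.shape[1])
    for j in range(P.shape[1]):
        out[j] = laminar_ttest(P[:, j], W[:, j], use_floor=use_floor)[0]
    return out


def group_wilcoxon(
    results: list[LaminarResult], null_value: float | np.ndarray = 0.0
) -> GroupResult:
    """Exact Wilcoxon signed-rank test on per-participant pial−white ROI
    differences, optionally against a shifted null (e.g. the mean value
    obtained under lead-field shuffling, per participant)."""
    diffs = np.array([r.difference for r in results])
    shifted = diffs - np.asarray(null_value, float)
    res = wilcoxon_exact(shifted)
    return GroupResult(
        differences=diffs,
        wilcoxon=res,
        n_superficial=int(sum(r.classification == "superficial" for r in results)),
        n_deep=int(sum(r.classification == "deep" for r in results)),
        null_value=float(np.mean(null_value)),
    )


# ---------------------------------------------------------------------------
# Condition comparisons

def condition_compare(
    trial_values: pd.DataFrame,
    conditions: list | None = None,
    test: str = "wilcoxon_paired",
    value_col: str = "value",
    condition_col: str = "condition",
    participant_col: str = "participant",
    correct_col: str = "correct",
) -> dict:
    """Compare band power between task conditions across participants.

    ``trial_values`` is tidy per-trial data; only correct trials enter the
    per-participant condition means.  Two conditions → paired exact Wilcoxon;
    three or more → Friedman with Tukey–Kramer rank follow-ups.  Participants
    missing a condition are dropped with a warning.
    """
    df = trial_values
    if correct_col in df.columns:
        df = df[df[correct_col].astype(bool)]
    if conditions is None:
        conditions = sorted(df[condition_col].unique())
    means = (
        df.groupby([participant_col, condition_col])[value_col]
        .mean()
        .unstack(condition_col)
        .reindex(columns=conditions)
    )
    incomplete = means.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} participant(s) missing a condition",
            stacklevel=2,
        )
        means = means[~incomplete]
    X = means.to_numpy()
    out = {"condition_means": means, "conditions": list(conditions)}
    if test == "wilcoxon_paired":
        if X.shape[1] != 2:
            raise ValueError("paired Wilcoxon requires exactly 2 conditions")
        d = X[:, 0] - X[:, 1]
        if np.allclose(d, 0):
            out.update({"W": float(len(d) * (len(d) + 1) / 4), "p": 1.0,
                        "mean_difference": 0.0})
        else:
            res = wilcoxon_exact(d)
            out.update({"W": res.W, "p": res.p, "mean_difference": float(d.mean()),
                        "sd_difference": float(d.std(ddof=1))})
    elif test == "friedman":
        fr = friedman_test(X)
        out.update(fr)
    else:
        raise ValueError(f"unknown test: {test}")
    return out


# ---------------------------------------------------------------------------
# Lead-field / depth confound analyses

def _partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Spearman partial correlation of x and y controlling for z (Pearson on
    ranks with the first-order partial formula)."""
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    rz = sstats.rankdata(z)
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        return 0.0
    return float((rxy - rxz * ryz) / denom)


def leadfield_bias_analysis(
    per_participant: list[pd.DataFrame],
    match_fraction: float = 0.01,
) -> dict:
    """Confound analyses relating laminar preference to lead-field strength
    and scalp distance.

    Each participant's frame has one row per ROI vertex pair with columns:
    ``t`` (vertexwise laminar t), ``rms_pial``/``rms_white`` (lead-field
    column RMS), ``depth_pial``/``depth_white`` (scalp distances, m) and
    ``diff`` (trial-mean pial−white unsigned fractional change).

    Four analyses: (a) per-participant Spearman partial correlations of t
    with the pial/white lead-field RMS ratio (controlling for depth) and
    with mean depth (controlling for RMS ratio), Fisher-z transformed and
    tested against zero across participants; (b) laminar test restricted to
    pairs whose lead-field RMS difference is within ``match_fraction`` of the
    overall RMS range; (c) laminar test restricted to pairs whose white
    vertex is closer to the scalp than its pial partner; (d) laminar test on
    the residuals of a robust regression of ``diff`` on the square root of
    mean scalp distance.
    """
    import statsmodels.api as sm

    z_lf, z_depth = [], []
    matched_t, closer_t, resid_t = [], [], []
    matched_skipped = 0
    for df in per_participant:
        ratio = df["rms_pial"].to_numpy() / df["rms_white"].to_numpy()
        depth = 0.5 * (df["depth_pial"] + df["depth_white"]).to_numpy()
        t = df["t"].to_numpy()
        r_lf = _partial_spearman(t, ratio, depth)
        r_dp = _partial_spearman(t, depth, ratio)
        z_lf.append(np.arctanh(np.clip(r_lf, -0.999999, 0.999999)))
        z_depth.append(np.arctanh(np.clip(r_dp, -0.999999, 0.999999)))

        rms_all = np.concatenate([df["rms_pial"], df["rms_white"]])
        rng_rms = rms_all.max() - rms_all.min()
        m_mask = (
            np.abs(df["rms_pial"] - df["rms_white"]).to_numpy()
            <= match_fraction * rng_rms
        )
        d = df["diff"].to_numpy()
        if m_mask.sum() >= 2:
            matched_t.append(float(sstats.ttest_1samp(d[m_mask], 0.0).statistic))
        else:
            matched_skipped += 1
        c_mask = (df["depth_white"] < df["depth_pial"]).to_numpy()
        if c_mask.sum() >= 2:
            closer_t.append(float(sstats.ttest_1samp(d[c_mask], 0.0).statistic))

        X = sm.add_constant(np.sqrt(np.maximum(depth, 0.0)))
        fit = sm.RLM(d, X, M=sm.robust.norms.HuberT()).fit()
        resid = d - fit.predict(X)
        resid_t.append(float(sstats.ttest_1samp(resid, 0.0).statistic))

    def _group(z: list[float]) -> dict:
        z = np.asarray(z)
        if len(z) < 2:
            return {"z_mean": float(np.mean(z)) if len(z) else np.nan,
                    "t": np.nan, "p": np.nan}
        res = sstats.ttest_1samp(z, 0.0)
        return {"z_mean": float(z.mean()), "t": float(res.statistic),
                "p": float(res.pvalue)}

    return {
        "leadfield_partial": _group(z_lf),
        "depth_partial": _group(z_depth),
        "matched_subset_t": np.asarray(matched_t),
        "matched_subset_skipped": matched_skipped,
        "white_closer_t": np.asarray(closer_t),
        "depth_residual_t": np.asarray(resid_t),
    }
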