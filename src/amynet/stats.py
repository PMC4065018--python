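"""Cohort-level inference.

Classical mixed-design (split-plot) ANOVA with one between-subject factor
(group) and one within-subject factor (network); post-hoc two-sample,
paired and one-sample t-tests with Bonferroni correction; voxel-wise group
t-maps with permutation-based cluster-extent correction; the across-subject
PiB vs r_GLOBAL correlation; and a subsampling control that re-runs group
statistics on size-matched random patient subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .volumes import VolumeMap


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# mixed ANOVA
# --------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    """F tests for group (between), network (within) and their interaction.

    The between-subject error stratum (subjects within groups) tests the
    group effect; the subject x network within-group stratum tests network
    and interaction.  No sphericity correction is applied.
    """

    F_group: float
    df_group: tuple[int, int]
    p_group: float
    F_network: float
    df_network: tuple[int, int]
    p_network: float
    F_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float
    cell_means: pd.DataFrame = field(repr=False, default=None)


def mixed_anova(values: pd.DataFrame, group: pd.Series) -> MixedAnovaResult:
    """Split-plot ANOVA on a complete subject x network table.

    ``values`` is indexed by subject with one column per network; ``group``
    gives each subject's between-subject label.
    """
    if values.isna().any().any():
        raise StatsError("missing cells: apply listwise deletion upstream of the ANOVA")
    group = group.reindex(values.index)
    if group.isna().any():
        raise StatsError("every subject needs a group label")
    glabels = list(dict.fromkeys(group))
    if any((group == g).sum() < 2 for g in glabels):
        raise StatsError("need >= 2 subjects per group")

    Y = values.to_numpy(dtype=float)
    n_sub, m = Y.shape
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    net_means = Y.mean(axis=0)

    ss_between_subj = m * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    ss_cells = 0.0
    ss_subj_within = 0.0
    for g in glabels:
        sel = (group == g).to_numpy()
        n_g = sel.sum()
        g_mean = Y[sel].mean()
        ss_group += m * n_g * (g_mean - grand) ** 2
        cell = Y[sel].mean(axis=0)
        ss_cells += n_g * np.sum((cell - grand) ** 2)
        ss_subj_within += m * np.sum((subj_means[sel] - g_mean) ** 2)
    ss_network = n_sub * np.sum((net_means - grand) ** 2)
    ss_inter = ss_cells - ss_group - ss_network
    ss_total = np.sum((Y - grand) ** 2)
    ss_err_within = ss_total - ss_between_subj - ss_network - ss_inter

    n_groups = len(glabels)
    df_group = (n_groups - 1, n_sub - n_groups)
    df_network = (m - 1, (n_sub - n_groups) * (m - 1))
    df_inter = ((n_groups - 1) * (m - 1), (n_sub - n_groups) * (m - 1))

    ms_group = ss_group / df_group[0]
    ms_subj = ss_subj_within / df_group[1]
    F_group = ms_group / ms_subj
    if m > 1:
        ms_network = ss_network / df_network[0]
        ms_inter = ss_inter / df_inter[0]
        ms_err = ss_err_within / df_network[1]
        F_network = ms_network / ms_err
        F_inter = ms_inter / ms_err
    else:  # a single within-subject level: no network or interaction test
        F_network = F_inter = float("nan")

    cells = pd.DataFrame(
        {g: Y[(group == g).to_numpy()].mean(axis=0) for g in glabels},
        index=values.columns).T
    def _p(F, df):
        return float(sps.f.sf(F, *df)) if np.isfinite(F) and df[0] > 0 and df[1] > 0 else float("nan")

    return MixedAnovaResult(
        F_group=float(F_group), df_group=df_group,
        p_group=_p(F_group, df_group),
        F_network=float(F_network), df_network=df_network,
        p_network=_p(F_network, df_network),
        F_interaction=float(F_inter), df_interaction=df_inter,
        p_interaction=_p(F_inter, df_inter),
        cell_means=cells)


# --------------------------------------------------------------------------
# t-tests and Bonferroni
# --------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    df: float
    p_raw: float
    p_corrected: float
    family_size: int
    kind: str  # two_sample | paired | one_sample

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.05


def _finish(stat, df, p, kind, family_size) -> TestResult:
    p_corr = min(1.0, p * family_size)
    return TestResult(float(stat), float(df), float(p), float(p_corr),
                      int(family_size), kind)


def two_sample_t(x, y, family_size: int = 1, welch: bool = False) -> TestResult:
    """Student (pooled-variance) two-sample t by default; Welch on request."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise StatsError("need >= 3 observations per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise StatsError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(x) + len(y) - 2
    return _finish(res.statistic, df, res.pvalue, "two_sample", family_size)


def paired_t(x, y, family_size: int = 1) -> TestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise StatsError("paired samples must have equal length")
    if len(x) < 3:
        raise StatsError("need >= 3 pairs")
    if np.ptp(x - y) == 0:
        raise StatsError("zero variance in paired differences; t undefined")
    res = sps.ttest_rel(x, y)
    return _finish(res.statistic, len(x) - 1, res.pvalue, "paired", family_size)


def one_sample_t(x, mu0: float = 0.0, family_size: int = 1) -> TestResult:
    x = np.asarray(x, float)
    if len(x) < 3:
        raise StatsError("need >= 3 observations")
    if np.ptp(x) == 0:
        raise StatsError("zero variance; t undefined")
    res = sps.ttest_1samp(x, mu0)
    return _finish(res.statistic, len(x) - 1, res.pvalue, "one_sample", family_size)


def bonferroni(p_values, family_size: int) -> np.ndarray:
    """Multiply by the family size and clip at 1."""
    p = np.asarray(p_values, dtype=float)
    if family_size < p.size:
        raise StatsError(f"family size {family_size} smaller than number of tests {p.size}")
    return np.minimum(1.0, p * family_size)


# --------------------------------------------------------------------------
# voxel-wise group t-maps with cluster-extent correction
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) indices
    extent: int
    peak_t: float
    p_corrected: float  # NaN when no permutation correction was run


@dataclass
class ClusterMap:
    t_map: VolumeMap
    threshold_t: float
    clusters: list  # of Cluster


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _tmap(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance two-sample t over the voxel axis.

    ``data`` has shape (n_subjects, ...); ``labels`` is boolean (True =
    first group)."""
    a, b = data[labels], data[~labels]
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return np.where(np.isfinite(t), t, 0.0)


def _cluster_extents(t: np.ndarray, thr: float, mask: np.ndarray):
    """26-connected supra-threshold clusters of |t| (both signs)."""
    out = []
    for sign in (1.0, -1.0):
        supra = (sign * t > thr) & mask
        lab, n = ndimage.label(supra, structure=_STRUCT26)
        for i in range(1, n + 1):
            vox = np.argwhere(lab == i)
            tv = t[lab == i]
            out.append((vox, len(vox), float(tv[np.argmax(np.abs(tv))])))
    return out


def voxelwise_group_tmap(maps: list[VolumeMap], group_labels,
                         height_p: float = 1e-4, min_extent: int = 100,
                         n_permutations: int = 0, mask: VolumeMap | None = None,
                         alpha: float = 0.05, seed: int = 0,
                         positive_group=None) -> ClusterMap:
    """Voxel-wise two-sample t-map with cluster-extent thresholding.

    ``positive_group`` names the label whose mean enters the t contrast with
    a positive sign (default: the alphabetically first label).  Supra-
    threshold voxels (two-sided at ``height_p``) are grouped into
    26-connected clusters; clusters smaller than ``min_extent`` are dropped.
    With ``n_permutations`` > 0, group labels are permuted and the maximum
    cluster extent under each permutation builds the null used to assign a
    family-wise corrected p-value to each observed cluster.
    """
    if isinstance(group_labels, np.ndarray) and group_labels.dtype == bool:
        labels = group_labels
    else:
        uniq = sorted(set(group_labels))
        if len(uniq) != 2:
            raise StatsError(f"need exactly two group labels, got {uniq}")
        pos = positive_group if positive_group is not None else uniq[0]
        labels = np.asarray([g == pos for g in group_labels])
    data = np.stack([m.values for m in maps])
    vmask = np.all(np.isfinite(data), axis=0)
    if mask is not None:
        vmask &= mask.values > 0
    na = int(labels.sum())
    nb = len(labels) - na
    if min(na, nb) < 2:
        raise StatsError("need >= 2 subjects per group for a voxel-wise t-map")
    dfree = na + nb - 2
    thr = float(sps.t.isf(height_p / 2, dfree))

    t_obs = _tmap(data, labels)
    t_obs[~vmask] = 0.0
    raw = [c for c in _cluster_extents(t_obs, thr, vmask) if c[1] >= min_extent]

    null_max = None
    if n_permutations > 0:
        if n_permutations < 100:
            import warnings
            warnings.warn("fewer than 100 permutations: corrected p-values are coarse")
        rng = np.random.default_rng(seed)
        null_max = np.zeros(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(labels)
            tp = _tmap(data, perm)
            tp[~vmask] = 0.0
            ext = [c[1] for c in _cluster_extents(tp, thr, vmask)]
            null_max[i] = max(ext) if ext else 0

    clusters = []
    for vox, extent, peak in raw:
        if null_max is not None:
            p_corr = float((np.sum(null_max >= extent) + 1) / (n_permutations + 1))
        else:
            p_corr = float("nan")
        clusters.append(Cluster(voxels=vox, extent=extent, peak_t=peak, p_corrected=p_corr))
    clusters.sort(key=lambda c: -c.extent)
    geom = dict(voxel_size_mm=maps[0].voxel_size_mm, origin=maps[0].origin)
    return ClusterMap(t_map=VolumeMap(np.where(vmask, t_obs, np.nan), **geom),
                      threshold_t=thr, clusters=clusters)


# --------------------------------------------------------------------------
# subject-level PiB vs r_GLOBAL correlation; subsampling control
# --------------------------------------------------------------------------

def pib_vs_rglobal_correlation(median_pib, r_global_values) -> tuple[float, TestResult]:
    """Pearson correlation across subjects (optionally pooled across
    networks) between median network PiB and r_GLOBAL."""
    x = np.asarray(median_pib, float)
    y = np.asarray(r_global_values, float)
    if len(x) < 5:
        raise StatsError("need >= 5 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    tstat = r * np.sqrt((len(x) - 2) / max(1e-300, 1 - r ** 2))
    return float(r), _finish(tstat, len(x) - 2, p, "two_sample", 1)


@dataclass
class SubsampleSummary:
    n_draws: int
    subset_size: int
    statistics: np.ndarray
    p_values: np.ndarray
    fraction_significant: dict  # alpha -> fraction of draws with p < alpha
    note: str = ""


def subsample_control(metric: pd.DataFrame, n_draws: int = 100, seed: int = 0,
                      alphas=(0.05, 0.01)) -> SubsampleSummary:
    """Group-size control: repeatedly draw a random patient subset matched in
    size to the control group and recompute the two-sample group test.

    ``metric`` needs columns ``value`` and ``group`` (one row per subject).
    """
    pat = metric.loc[metric["group"] == "patient", "value"].to_numpy(float)
    con = metric.loc[metric["group"] == "control", "value"].to_numpy(float)
    if len(pat) == len(con):
        t = two_sample_t(pat, con)
        return SubsampleSummary(1, len(con), np.array([t.statistic]),
                                np.array([t.p_raw]),
                                {a: float(t.p_raw < a) for a in alphas},
                                note="groups already matched in size; no subsampling done")
    if len(pat) < len(con):
        raise StatsError("subsampling assumes more patients than controls")
    rng = np.random.default_rng(seed)
    stats_, ps = np.zeros(n_draws), np.zeros(n_draws)
    for i in range(n_draws):
        sub = rng.choice(pat, size=len(con), replace=False)
        t = two_sample_t(sub, con)
        stats_[i], ps[i] = t.statistic, t.p_raw
    frac = {a: float(np.mean(ps < a)) for a in alphas}
    return SubsampleSummary(n_draws, len(con), stats_, ps, frac)
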