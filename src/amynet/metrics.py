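"""Per-subject, per-network scalar metrics.

For each subject and network: the supra-threshold network voxel set, median
PiB uptake across it, the whole-network PiB-connectivity spatial correlation
(r_GLOBAL, Fisher-transformed), the network connectivity score, OLS
residualization against grey-matter density / age / gender, and
PiB-positivity classification from the neocortical composite SUVR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SUVR_CUTOFF, SubjectRecord

#: below this voxel count a network is too small for stable spatial statistics
MIN_NETWORK_VOXELS = 200

#: correlations are clipped here before atanh so Fisher z stays finite
FISHER_CLIP = 1.0 - 1e-7


class MetricError(ValueError):
    """Degenerate input to a metric (empty set, zero variance, ...)."""


@dataclass
class NetworkVoxelSet:
    """All voxels of one subject's network (connectivity z above threshold)
    with the aligned per-voxel connectivity and PiB value vectors."""

    subject_id: str
    network_name: str
    voxel_indices: np.ndarray  # (n, 3) int lattice coordinates
    ifc_values: np.ndarray     # connectivity z per voxel (all > threshold)
    pib_values: np.ndarray     # PiB uptake per voxel
    grid_dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = len(self.voxel_indices)
        if not (len(self.ifc_values) == len(self.pib_values) == n):
            raise MetricError("voxel index / value vectors must be aligned")

    def __len__(self) -> int:
        return len(self.ifc_values)


@dataclass
class GlobalCorrelationResult:
    """Whole-network PiB-connectivity Pearson correlation for one
    subject x network, with its Fisher transform."""

    subject_id: str
    network_name: str
    r_global: float
    fisher_z: float
    n_voxels: int


@dataclass
class CovariateModel:
    """OLS fit of a network metric on median grey-matter density, age and
    gender (F=1, M=0), used to residualize the metric."""

    network_name: str
    fit_scope: str  # "pooled" | "per_group"
    coefficients: dict  # scope key -> {intercept, gm_median, age, gender}


def select_network_voxels(subject: SubjectRecord, network_name: str,
                          z_threshold: float = 1.0,
                          min_voxels: int = MIN_NETWORK_VOXELS) -> NetworkVoxelSet:
    """Voxels with connectivity z strictly above ``z_threshold``, paired with
    the subject's PiB values at the same voxels."""
    zmap = subject.connectivity_maps[network_name]
    with np.errstate(invalid="ignore"):
        mask = zmap.values > z_threshold
    n = int(mask.sum())
    if n < min_voxels:
        raise MetricError(
            f"network {network_name!r} of subject {subject.subject_id}: only {n} voxels "
            f"exceed z={z_threshold:g} (minimum {min_voxels}); degenerate network")
    idx = np.argwhere(mask)
    return NetworkVoxelSet(
        subject_id=subject.subject_id, network_name=network_name,
        voxel_indices=idx, ifc_values=zmap.values[mask],
        pib_values=subject.pib_map.values[mask],
        grid_dims=zmap.shape, voxel_size_mm=zmap.voxel_size_mm)


def log_transform_ifc(values: np.ndarray) -> np.ndarray:
    """Natural log of connectivity values (reduces the skew induced by
    thresholding at z > 1; all inputs must be positive)."""
    values = np.asarray(values, dtype=np.float64)
    if np.any(values <= 0):
        raise MetricError("log transform requires strictly positive connectivity values")
    return np.log(values)


def median_network_pib(nvs: NetworkVoxelSet) -> float:
    """Median PiB uptake across the network's voxels."""
    if len(nvs) == 0:
        raise MetricError("empty network voxel set")
    return float(np.median(nvs.pib_values))


def network_connectivity_score(nvs: NetworkVoxelSet) -> float:
    """Median log-transformed connectivity z across the network."""
    if len(nvs) == 0:
        raise MetricError("empty network voxel set")
    return float(np.median(log_transform_ifc(nvs.ifc_values)))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """atanh with clipping so perfect correlations stay finite."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def r_global(nvs: NetworkVoxelSet, log_transform: bool = True) -> GlobalCorrelationResult:
    """Pearson correlation between (log-)connectivity and PiB uptake over the
    whole network, plus its Fisher transform."""
    if len(nvs) < MIN_NETWORK_VOXELS:
        raise MetricError(f"need >= {MIN_NETWORK_VOXELS} voxels, got {len(nvs)}")
    x = log_transform_ifc(nvs.ifc_values) if log_transform else nvs.ifc_values
    y = nvs.pib_values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MetricError("zero variance in connectivity or PiB vector; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    return GlobalCorrelationResult(nvs.subject_id, nvs.network_name,
                                   r_global=r, fisher_z=float(np.arctanh(r)),
                                   n_voxels=len(nvs))


def classify_pib_status(neocortical_suvr: float, cutoff: float = SUVR_CUTOFF) -> str:
    """PiB-positivity from the neocortical composite SUVR (positive iff
    SUVR >= cutoff, default 1.15)."""
    if neocortical_suvr <= 0:
        raise MetricError("SUVR must be positive")
    return "positive" if neocortical_suvr >= cutoff else "negative"


# --------------------------------------------------------------------------
# covariate residualization
# --------------------------------------------------------------------------

def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    gender = covariates["gender"]
    if gender.dtype == object:
        gender = gender.map({"F": 1.0, "M": 0.0})
    X = np.column_stack([
        np.ones(len(covariates)),
        covariates["gm_median"].to_numpy(dtype=float),
        covariates["age"].to_numpy(dtype=float),
        gender.to_numpy(dtype=float),
    ])
    return X


def residualize(metric: np.ndarray, covariates: pd.DataFrame,
                scope: str = "pooled", network_name: str = "") -> tuple[np.ndarray, CovariateModel]:
    """OLS-residualize a per-subject metric against grey-matter density, age
    and gender.

    ``covariates`` needs columns ``gm_median``, ``age``, ``gender`` (and
    ``group`` when ``scope == "per_group"``).  Residuals are orthogonal to
    every covariate within each fitted scope.

    ``pooled`` fits one OLS across all subjects (single intercept; residuals
    are globally demeaned).  ``per_group`` fits covariate slopes separately
    within each group and subtracts only the covariate contributions, adding
    the group mean back: group mean differences survive residualization (a
    per-group fit that also removed its intercept would annihilate exactly
    the group effects tested downstream), while residuals stay uncorrelated
    with every covariate within each group.  With groups differing in age,
    the pooled fit lets the age slope absorb part of a true group effect;
    per_group does not.
    """
    metric = np.asarray(metric, dtype=np.float64)
    if scope not in ("pooled", "per_group"):
        raise ValueError(f"unknown scope {scope!r}")
    resid = np.full_like(metric, np.nan)
    coefs: dict[str, dict] = {}
    if scope == "pooled":
        parts = {"pooled": np.ones(len(metric), dtype=bool)}
    else:
        parts = {g: (covariates["group"] == g).to_numpy() for g in covariates["group"].unique()}
    for key, sel in parts.items():
        X = _design_matrix(covariates.loc[sel])
        y = metric[sel]
        if len(y) < 5:
            raise MetricError(f"need >= 5 subjects per fitted model, got {len(y)} in {key!r}")
        # constant covariates carry no information beyond the intercept:
        # drop them so the fit degrades gracefully to demeaning
        names = ["intercept", "gm_median", "age", "gender"]
        keep = [0] + [i for i in range(1, X.shape[1]) if np.ptp(X[:, i]) > 0]
        Xk = X[:, keep]
        if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
            raise MetricError("collinear covariates: design matrix is rank-deficient")
        beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        resid[sel] = y - Xk @ beta
        if scope == "per_group":
            resid[sel] += y.mean()  # keep the group mean (see docstring)
        coefs[key] = {names[i]: float(b) for i, b in zip(keep, beta)}
    model = CovariateModel(network_name=network_name, fit_scope=scope, coefficients=coefs)
    return resid, model
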