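"""Local PiB-connectivity correlation via a volumetric searchlight.

The whole-network (global) coupling is first removed by Gram-Schmidt
orthogonalization — projecting one voxel-value vector off the other so their
correlation across the entire network is exactly zero.  A sphere of given
radius (default 6 mm) then moves over every network voxel; within each
sphere the Pearson correlation between the orthogonalized PiB and
connectivity values over the *in-network* neighbors is computed, Fisher
transformed, and recorded at the central voxel (r_LOCAL).  Centers with
fewer than ``min_neighbors`` in-network neighbors (default 25) are skipped
as unreliable boundary estimates.

Orthogonalization is asymmetric, so the analysis is run in both directions
(PiB decorrelated w.r.t. connectivity, and vice versa) and the two Fisher-z
maps are averaged voxel-wise over the voxels recorded in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import FISHER_CLIP, MetricError, NetworkVoxelSet, log_transform_ifc
from .volumes import SphereOffsets, VolumeMap

PIB_WRT_IFC = "pib_wrt_ifc"
IFC_WRT_PIB = "ifc_wrt_pib"

#: a neighborhood variance below this (per voxel, on demeaned O(1) data)
#: counts as zero variance and the center voxel is skipped
_VAR_EPS = 1e-12


@dataclass
class OrthogonalizedSet:
    """A network voxel set whose PiB / connectivity vectors have been
    decorrelated across the whole network (one direction)."""

    base: NetworkVoxelSet
    pib_residual: np.ndarray
    ifc_residual: np.ndarray
    direction: str


@dataclass
class SearchlightMap:
    """Per-voxel Fisher-z r_LOCAL values for one subject x network.

    Unrecorded voxels carry NaN; ``valid_mask`` marks recorded voxels and
    ``n_neighbors`` holds each network voxel's in-network neighborhood size.
    """

    subject_id: str
    network_name: str
    r_local: VolumeMap
    valid_mask: VolumeMap
    n_neighbors: VolumeMap
    radius_mm: float
    min_neighbors: int
    n_skipped_few_neighbors: int = 0
    n_skipped_zero_variance: int = 0


def gram_schmidt(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Demean both vectors and project ``a`` off ``b``.

    Returns a' = a_c - (<a_c, b_c>/<b_c, b_c>) b_c with a_c, b_c the demeaned
    vectors; corr(a', b) is zero to numerical precision.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = bc @ bc
    if denom <= 0:
        raise MetricError("reference vector has zero variance; cannot orthogonalize")
    return ac - (ac @ bc) / denom * bc


def orthogonalize(nvs: NetworkVoxelSet, direction: str = PIB_WRT_IFC,
                  log_transform: bool = True) -> OrthogonalizedSet:
    """Build the orthogonalized pair for one direction.

    The connectivity vector is log-transformed by default (consistent with
    the whole-network correlation).  The vector being decorrelated becomes
    the Gram-Schmidt residual; the reference vector is demeaned only.
    """
    ifc = log_transform_ifc(nvs.ifc_values) if log_transform else nvs.ifc_values.astype(float)
    pib = nvs.pib_values.astype(float)
    if direction == PIB_WRT_IFC:
        pib_res = gram_schmidt(pib, ifc)
        ifc_res = ifc - ifc.mean()
    elif direction == IFC_WRT_PIB:
        ifc_res = gram_schmidt(ifc, pib)
        pib_res = pib - pib.mean()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return OrthogonalizedSet(base=nvs, pib_residual=pib_res, ifc_residual=ifc_res,
                             direction=direction)


def _shift_slices(offset, shape):
    """dst/src slice tuples realizing out[dst] += arr[src] for one offset."""
    dst, src = [], []
    for d, n in zip(offset, shape):
        if d >= 0:
            dst.append(slice(0, max(0, n - d)))
            src.append(slice(min(d, n), n))
        else:
            dst.append(slice(min(-d, n), n))
            src.append(slice(0, max(0, n + d)))
    return tuple(dst), tuple(src)


def neighborhood_counts(nvs: NetworkVoxelSet, offsets: SphereOffsets) -> np.ndarray:
    """In-network neighborhood size for every network voxel (full grid;
    zero outside the network)."""
    mask = np.zeros(nvs.grid_dims, dtype=bool)
    mask[tuple(nvs.voxel_indices.T)] = True
    m = mask.astype(np.float64)
    count = np.zeros_like(m)
    for off in offsets.offsets:
        dst, src = _shift_slices(off, mask.shape)
        count[dst] += m[src]
    count[~mask] = 0
    return count.astype(np.int64)


def searchlight_rlocal(oset: OrthogonalizedSet, offsets: SphereOffsets,
                       min_neighbors: int = 25) -> SearchlightMap:
    """Fisher-z map of local Pearson correlations over sphere neighborhoods.

    Neighborhoods contain in-network voxels only; centers with fewer than
    ``min_neighbors`` of them, or with a zero-variance neighborhood in either
    vector, are skipped (the latter tallied, not raised).
    """
    nvs = oset.base
    shape = nvs.grid_dims
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(nvs.voxel_indices.T)] = True

    # crop to the network's bounding box (padded by the sphere extent)
    lo = nvs.voxel_indices.min(axis=0)
    hi = nvs.voxel_indices.max(axis=0) + 1
    pad = np.abs(offsets.offsets).max(axis=0) if len(offsets) else np.zeros(3, int)
    lo = np.maximum(lo - pad, 0)
    hi = np.minimum(hi + pad, shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    bmask = mask[box]
    bshape = bmask.shape

    X = np.zeros(bshape)
    Y = np.zeros(bshape)
    X[bmask] = _scatter(nvs, oset.pib_residual, mask)[box][bmask]
    Y[bmask] = _scatter(nvs, oset.ifc_residual, mask)[box][bmask]

    m = bmask.astype(np.float64)
    acc = {k: np.zeros(bshape) for k in ("n", "sx", "sy", "sxx", "syy", "sxy")}
    XX, YY, XY = X * X, Y * Y, X * Y
    for off in offsets.offsets:
        dst, src = _shift_slices(off, bshape)
        acc["n"][dst] += m[src]
        acc["sx"][dst] += X[src]
        acc["sy"][dst] += Y[src]
        acc["sxx"][dst] += XX[src]
        acc["syy"][dst] += YY[src]
        acc["sxy"][dst] += XY[src]

    n = acc["n"]
    with np.errstate(invalid="ignore", divide="ignore"):
        varx = acc["sxx"] - acc["sx"] ** 2 / n
        vary = acc["syy"] - acc["sy"] ** 2 / n
        cov = acc["sxy"] - acc["sx"] * acc["sy"] / n
        r = cov / np.sqrt(varx * vary)

    enough = bmask & (n >= min_neighbors)
    nonflat = (varx > _VAR_EPS * n) & (vary > _VAR_EPS * n)
    valid = enough & nonflat
    n_few = int(bmask.sum() - enough.sum())
    n_flat = int(enough.sum() - valid.sum())

    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    full_z = np.full(shape, np.nan)
    tmp = np.full(bshape, np.nan)
    tmp[valid] = z[valid]
    full_z[box] = tmp
    full_valid = np.zeros(shape)
    tmp = np.zeros(bshape)
    tmp[valid] = 1.0
    full_valid[box] = tmp
    full_counts = np.zeros(shape)
    tmp = np.zeros(bshape)
    tmp[bmask] = n[bmask]
    full_counts[box] = tmp

    geom = dict(voxel_size_mm=nvs.voxel_size_mm)
    return SearchlightMap(
        subject_id=nvs.subject_id, network_name=nvs.network_name,
        r_local=VolumeMap(full_z, **geom),
        valid_mask=VolumeMap(full_valid, **geom),
        n_neighbors=VolumeMap(full_counts, **geom),
        radius_mm=offsets.radius_mm, min_neighbors=min_neighbors,
        n_skipped_few_neighbors=n_few, n_skipped_zero_variance=n_flat)


def _scatter(nvs: NetworkVoxelSet, values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros(nvs.grid_dims)
    out[tuple(nvs.voxel_indices.T)] = values
    return out


def symmetric_rlocal(nvs: NetworkVoxelSet, offsets: SphereOffsets,
                     min_neighbors: int = 25, log_transform: bool = True) -> SearchlightMap:
    """Direction-averaged searchlight map.

    Runs the orthogonalization and searchlight in both directions and
    averages the two Fisher-z maps voxel-wise; voxels recorded in only one
    direction are dropped.
    """
    maps = [
        searchlight_rlocal(orthogonalize(nvs, d, log_transform), offsets, min_neighbors)
        for d in (PIB_WRT_IFC, IFC_WRT_PIB)
    ]
    v1 = maps[0].valid_mask.values > 0
    v2 = maps[1].valid_mask.values > 0
    both = v1 & v2
    z = np.full(nvs.grid_dims, np.nan)
    z[both] = 0.5 * (maps[0].r_local.values[both] + maps[1].r_local.values[both])
    geom = dict(voxel_size_mm=nvs.voxel_size_mm)
    return SearchlightMap(
        subject_id=nvs.subject_id, network_name=nvs.network_name,
        r_local=VolumeMap(z, **geom),
        valid_mask=VolumeMap(both.astype(float), **geom),
        n_neighbors=maps[0].n_neighbors,
        radius_mm=offsets.radius_mm, min_neighbors=min_neighbors,
        n_skipped_few_neighbors=maps[0].n_skipped_few_neighbors,
        n_skipped_zero_variance=max(m.n_skipped_zero_variance for m in maps))


def median_rlocal(slmap: SearchlightMap) -> float:
    """Median Fisher-z r_LOCAL over the recorded voxels."""
    valid = slmap.valid_mask.values > 0
    if not valid.any():
        raise MetricError("searchlight map has no recorded voxels")
    return float(np.median(slmap.r_local.values[valid]))
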