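"""Synthetic multimodal cohorts with known amyloid-connectivity coupling.

Real studies of this kind hold, per participant, one intrinsic-connectivity
z-score map per network (back-projected ICA components), one PiB
standardized-uptake-ratio map, and one grey-matter density map, all spatially
normalized to a common grid.  No such cohort is bundled here; instead this
module generates cohorts whose maps carry, by construction, the statistical
structure the analysis is designed to detect:

* patients have globally elevated PiB uptake;
* within each *coupled* network, PiB tracks the large-scale connectivity
  topography (network cores carry more amyloid than the periphery) — a
  positive whole-network spatial correlation;
* superimposed on that, PiB is *locally* anti-correlated with the subject's
  fine-scale connectivity fluctuations, amplitude-weighted toward network
  cores — a negative neighborhood-scale correlation;
* one control network (by default the last, a primary-sensory stand-in)
  receives neither coupling, and healthy controls receive neither coupling
  in any network.

The two couplings live at different spatial scales (a wide-smoothed template
field for the global term; the high-pass connectivity fluctuation for the
local term), so each can be injected, recovered and dialed independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import VolumeMap, VolumeError, read_volume, smooth_volume, write_volume

PATIENT = "patient"
CONTROL = "control"
GROUPS = (PATIENT, CONTROL)

#: neocortical SUVR cut-off separating PiB-positive from PiB-negative
SUVR_CUTOFF = 1.15


class DesignError(ValueError):
    """Invalid cohort design."""


class CohortIOError(ValueError):
    """Inconsistent cohort on disk (manifest/file mismatch)."""


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def _default_blob_spec() -> dict[str, list[tuple[tuple[float, float, float], float, float]]]:
    """Blob layout for the default seven-network design.

    Six coupled fronto-parietal-like networks of two Gaussian nodes each,
    plus one single-node primary-sensory-like control network (pAN) placed
    well away from the coupled group so the wide-scale coupling field is
    essentially flat across it.  Centers in mm on a 112 x 144 x 112 mm box.
    """
    sd, amp = 12.0, 3.5
    spec = {
        "aDMN": [((30, 28, 30), sd, amp), ((30, 64, 30), sd, amp)],
        "pDMN": [((82, 28, 30), sd, amp), ((82, 64, 30), sd, amp)],
        "lATN": [((30, 28, 82), sd, amp), ((30, 64, 82), sd, amp)],
        "rATN": [((82, 28, 82), sd, amp), ((82, 64, 82), sd, amp)],
        "dATN": [((56, 28, 56), sd, amp), ((56, 64, 56), sd, amp)],
        "SN": [((30, 46, 56), sd, amp), ((82, 46, 56), sd, amp)],
        "pAN": [((56, 120, 56), 14.0, 4.0)],
    }
    return spec


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort.

    Group-dependent parameters are mappings keyed by ``"patient"`` /
    ``"control"``.  ``b_global`` scales the network-scale positive
    PiB-connectivity coupling, ``c_local`` the neighborhood-scale negative
    coupling; both must be non-negative.  ``coupled`` flags which networks
    receive the couplings (the control network does not).
    """

    n_patients: int = 23
    n_controls: int = 12
    grid_dims: tuple[int, int, int] = (56, 72, 56)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    blob_spec: dict = field(default_factory=_default_blob_spec)
    coupled: dict | None = None  # name -> bool; default: all but "pAN"
    b_global: dict = field(default_factory=lambda: {PATIENT: 0.35, CONTROL: 0.0})
    c_local: dict = field(default_factory=lambda: {PATIENT: 0.02, CONTROL: 0.0})
    pib_baseline: dict = field(default_factory=lambda: {PATIENT: 1.4, CONTROL: 1.0})
    suvr_mean: dict = field(default_factory=lambda: {PATIENT: 1.6, CONTROL: 1.02})
    suvr_sd: dict = field(default_factory=lambda: {PATIENT: 0.25, CONTROL: 0.05})
    #: between-subject amyloid-burden heterogeneity (lognormal CV); scales a
    #: subject's baseline elevation, both couplings, and the composite SUVR,
    #: so heavier-burden patients couple more strongly (the across-subject
    #: PiB vs r_GLOBAL gradient rides on this)
    burden_cv: dict = field(default_factory=lambda: {PATIENT: 0.3, CONTROL: 0.0})
    noise_sd_ifc: float = 0.4
    noise_sd_pib: float = 0.15
    noise_fwhm_mm: float = 6.0
    wide_fwhm_mm: float = 16.0
    local_fwhm_mm: float = 6.0
    age_mean: dict = field(default_factory=lambda: {PATIENT: 69.3, CONTROL: 63.8})
    age_sd: dict = field(default_factory=lambda: {PATIENT: 7.4, CONTROL: 5.15})
    p_female: dict = field(default_factory=lambda: {PATIENT: 9 / 23, CONTROL: 0.5})
    seed: int = 0
    min_template_voxels: int = 500  # supra-threshold floor per network

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise DesignError("both groups need at least one subject")
        if self.coupled is None:
            names = list(self.blob_spec)
            self.coupled = {n: (n != "pAN") for n in names}
        for g in GROUPS:
            if self.b_global[g] < 0 or self.c_local[g] < 0:
                raise DesignError("b_global and c_local must be non-negative")
        for name, blobs in self.blob_spec.items():
            for _, sd_mm, amp in blobs:
                if sd_mm <= 0:
                    raise DesignError(f"blob sd must be positive in network {name!r}")

    @property
    def network_names(self) -> list[str]:
        return list(self.blob_spec)

    @property
    def n_networks(self) -> int:
        return len(self.blob_spec)


def single_network_design(n_patients: int = 10, n_controls: int = 10,
                          b_global_patient: float = 0.0,
                          c_local_patient: float = 0.0,
                          pib_elevated: bool = False,
                          seed: int = 0) -> CohortDesign:
    """A compact one-network design on a 24^3 grid (~1,700 network voxels).

    Used for calibration experiments where many cohorts must be simulated;
    all couplings default to zero (a null cohort).
    """
    baseline = {PATIENT: 1.4 if pib_elevated else 1.0, CONTROL: 1.0}
    return CohortDesign(
        n_patients=n_patients, n_controls=n_controls,
        grid_dims=(24, 24, 24),
        blob_spec={"net": [((24.0, 24.0, 24.0), 10.0, 3.0)]},
        coupled={"net": True},
        b_global={PATIENT: b_global_patient, CONTROL: 0.0},
        c_local={PATIENT: c_local_patient, CONTROL: 0.0},
        pib_baseline=baseline,
        seed=seed,
    )


# --------------------------------------------------------------------------
# subjects
# --------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One participant: per-network connectivity maps, PiB map, grey matter
    map, demographics and the neocortical composite SUVR."""

    subject_id: str
    group: str
    connectivity_maps: dict  # network name -> VolumeMap of z-scores
    pib_map: VolumeMap
    gm_map: VolumeMap
    age: float
    gender: str  # "F" | "M"
    neocortical_suvr: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DesignError(f"unknown group {self.group!r}")
        if self.neocortical_suvr <= 0:
            raise DesignError("neocortical SUVR must be positive")
        shapes = {m.shape for m in self.connectivity_maps.values()}
        shapes |= {self.pib_map.shape, self.gm_map.shape}
        if len(shapes) != 1:
            raise DesignError("all maps of a subject must share one grid")

    @property
    def network_names(self) -> list[str]:
        return list(self.connectivity_maps)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def make_network_templates(design: CohortDesign) -> dict[str, VolumeMap]:
    """Gaussian-blob network templates (stand-ins for group ICA maps).

    Each template is the blob-wise sum clipped at the network's maximum blob
    amplitude, so values lie in [0, max amplitude].
    """
    nx, ny, nz = design.grid_dims
    vx, vy, vz = design.voxel_size_mm
    xs = np.arange(nx)[:, None, None] * vx
    ys = np.arange(ny)[None, :, None] * vy
    zs = np.arange(nz)[None, None, :] * vz
    templates: dict[str, VolumeMap] = {}
    for name, blobs in design.blob_spec.items():
        t = np.zeros(design.grid_dims)
        amp_max = 0.0
        for center, sd_mm, amp in blobs:
            cx, cy, cz = center
            d2 = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
            t += amp * np.exp(-d2 / (2.0 * sd_mm ** 2))
            amp_max = max(amp_max, amp)
        t = np.minimum(t, amp_max)
        n_supra = int((t > 1.0).sum())
        if n_supra < design.min_template_voxels:
            raise DesignError(
                f"network template {name!r} has only {n_supra} voxels above 1.0 "
                f"(need >= {design.min_template_voxels}); too small for searchlight analysis"
            )
        templates[name] = VolumeMap(t, design.voxel_size_mm)
    return templates


def _smooth_noise(rng: np.random.Generator, design: CohortDesign, sd: float) -> np.ndarray:
    """Spatially smooth Gaussian field rescaled to marginal SD ``sd``."""
    white = rng.standard_normal(design.grid_dims)
    if design.noise_fwhm_mm > 0:
        f = smooth_volume(VolumeMap(white, design.voxel_size_mm), design.noise_fwhm_mm).values
    else:
        f = white
    f = f - f.mean()
    s = f.std()
    return f * (sd / s) if s > 0 else f


def _reflected_normal(rng, mean, sd, cutoff, side) -> float:
    """Normal draw reflected to one side of ``cutoff`` (keeps group
    separation exact: patients always >= cutoff, controls always < cutoff)."""
    x = rng.normal(mean, sd)
    if side == "above":
        return cutoff + abs(x - cutoff)
    return max(cutoff - abs(x - cutoff) - 1e-9, 0.05)


def generate_cohort(design: CohortDesign) -> list[SubjectRecord]:
    """Generate the full cohort; bit-reproducible from ``design.seed``."""
    templates = make_network_templates(design)
    names = design.network_names
    coupled_names = [n for n in names if design.coupled[n]]
    if coupled_names:
        mean_template = np.mean([templates[n].values for n in coupled_names], axis=0)
        wide = smooth_volume(VolumeMap(mean_template, design.voxel_size_mm),
                             design.wide_fwhm_mm).values
        wide = wide - wide.mean()  # centered so pib_baseline keeps its meaning
    else:
        wide = np.zeros(design.grid_dims)

    weights = {n: templates[n].values / max(a for _, _, a in design.blob_spec[n])
               for n in coupled_names}

    ss = np.random.SeedSequence(design.seed)
    groups = [PATIENT] * design.n_patients + [CONTROL] * design.n_controls
    children = ss.spawn(len(groups))
    subjects: list[SubjectRecord] = []
    counters = {PATIENT: 0, CONTROL: 0}
    base_ref = design.pib_baseline[CONTROL]
    for grp, child in zip(groups, children):
        rng = np.random.default_rng(child)
        counters[grp] += 1
        sid = f"{'pat' if grp == PATIENT else 'con'}{counters[grp]:03d}"

        cv = design.burden_cv[grp]
        # mean-one lognormal burden factor for this subject
        burden = float(np.exp(rng.normal(-0.5 * cv ** 2, cv))) if cv > 0 else 1.0

        conn: dict[str, VolumeMap] = {}
        local_term = np.zeros(design.grid_dims)
        for name in names:
            z = templates[name].values + _smooth_noise(rng, design, design.noise_sd_ifc)
            conn[name] = VolumeMap(z, design.voxel_size_mm)
            if name in weights:
                z_low = smooth_volume(conn[name], design.local_fwhm_mm).values
                local_term += weights[name] * (z - z_low)
        if coupled_names and design.c_local[grp] > 0:
            # normalize over network cores so c_local is the SD (in SUVR
            # units) of the injected local component there
            core = np.maximum.reduce([weights[n] for n in weights]) > 0.25
            s = local_term[core].std()
            if s > 0:
                local_term = local_term / s

        pib = (base_ref + (design.pib_baseline[grp] - base_ref) * burden
               + design.b_global[grp] * burden * wide
               - design.c_local[grp] * burden * local_term
               + _smooth_noise(rng, design, design.noise_sd_pib))

        age = float(np.clip(rng.normal(design.age_mean[grp], design.age_sd[grp]), 45, 95))
        gender = "F" if rng.random() < design.p_female[grp] else "M"
        gm = np.clip(0.75 - 0.004 * (age - 65.0)
                     + _smooth_noise(rng, design, 0.03), 0.05, 0.95)
        if grp == PATIENT:
            suvr_center = SUVR_CUTOFF + (design.suvr_mean[grp] - SUVR_CUTOFF) * burden
        else:
            suvr_center = design.suvr_mean[grp]
        suvr = _reflected_normal(rng, suvr_center, design.suvr_sd[grp],
                                 SUVR_CUTOFF, "above" if grp == PATIENT else "below")

        subjects.append(SubjectRecord(
            subject_id=sid, group=grp, connectivity_maps=conn,
            pib_map=VolumeMap(pib, design.voxel_size_mm),
            gm_map=VolumeMap(gm, design.voxel_size_mm),
            age=age, gender=gender, neocortical_suvr=float(suvr)))
    return subjects


# --------------------------------------------------------------------------
# cohort I/O
# --------------------------------------------------------------------------

def write_cohort(subjects: list[SubjectRecord], directory) -> str:
    """Write one NIfTI per map plus a CSV manifest; returns the manifest path.

    Manifest columns: subject_id, group, age, gender, neocortical_suvr,
    pib_path, gm_path, net1_path, ...; network names go to a sidecar
    ``cohort_meta.json`` in the same directory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortIOError(f"duplicate subject ids: {dupes}")
    names = subjects[0].network_names
    rows = []
    for s in subjects:
        if s.network_names != names:
            raise CohortIOError(f"subject {s.subject_id} has mismatched networks")
        row = {"subject_id": s.subject_id, "group": s.group, "age": s.age,
               "gender": s.gender, "neocortical_suvr": s.neocortical_suvr}
        row["pib_path"] = f"{s.subject_id}_pib.nii.gz"
        row["gm_path"] = f"{s.subject_id}_gm.nii.gz"
        write_volume(s.pib_map, directory / row["pib_path"])
        write_volume(s.gm_map, directory / row["gm_path"])
        for i, name in enumerate(names, start=1):
            p = f"{s.subject_id}_net{i}.nii.gz"
            write_volume(s.connectivity_maps[name], directory / p)
            row[f"net{i}_path"] = p
        rows.append(row)
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    (directory / "cohort_meta.json").write_text(json.dumps({"network_names": names}))
    return str(manifest)


def load_cohort(manifest_path) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CohortIOError(f"manifest not found: {manifest_path}")
    directory = manifest_path.parent
    df = pd.read_csv(manifest_path)
    if df["subject_id"].duplicated().any():
        raise CohortIOError("duplicate subject ids in manifest")
    meta_path = directory / "cohort_meta.json"
    if meta_path.exists():
        names = json.loads(meta_path.read_text())["network_names"]
    else:
        n_nets = sum(c.startswith("net") and c.endswith("_path") for c in df.columns)
        names = [f"net{i}" for i in range(1, n_nets + 1)]
    subjects = []
    for _, row in df.iterrows():
        def _read(rel):
            p = directory / rel
            if not p.exists():
                raise CohortIOError(f"manifest references missing file: {p}")
            return read_volume(p)
        conn = {name: _read(row[f"net{i}_path"]) for i, name in enumerate(names, start=1)}
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            connectivity_maps=conn, pib_map=_read(row["pib_path"]),
            gm_map=_read(row["gm_path"]), age=float(row["age"]),
            gender=str(row["gender"]), neocortical_suvr=float(row["neocortical_suvr"])))
    return subjects
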