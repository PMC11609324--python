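"""Mapping of meta-analytic emotion-regulation ROIs onto a labeled parcellation.

The four emotion-regulation networks (ERN1..ERN4) are defined by peak MNI
coordinates (or full cluster masks) of meta-analytically derived regions.
This module places a sphere of configurable radius around each peak (or
resamples each cluster mask), counts how many ROI voxels fall into each
parcel of a labeled volume, filters weak overlaps, and assigns each parcel
uniquely to the network with the largest voxel overlap.

The packaged default network definition (``data/ern_rois_synthetic.tsv``) is
a synthetic stand-in: 36 rows with approximate anatomical MNI coordinates
for the region labels of the four networks, suitable for exercising the
pipeline but not a published coordinate table.

Coordinates are MNI millimetres; voxel indices are 0-based; the NIfTI affine
is the single source of truth for the conversion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NETWORK_IDS = ("ERN1", "ERN2", "ERN3", "ERN4")

WITHIN_KEYS = ("ERN1", "ERN2", "ERN3", "ERN4")
BETWEEN_KEYS = ("ERN12", "ERN13", "ERN14", "ERN23", "ERN24", "ERN34")
FEATURE_KEYS = WITHIN_KEYS + BETWEEN_KEYS


class AtlasError(ValueError):
    """Raised on violated atlas-mapping contracts."""


@dataclass
class NetworkDefinition:
    """Table of meta-analytic ROI records (one row per ROI peak)."""

    table: pd.DataFrame  # columns: network, label, x, y, z [, mask_path]

    def __post_init__(self) -> None:
        t = self.table
        required = {"network", "label", "x", "y", "z"}
        missing = required - set(t.columns)
        if missing:
            raise AtlasError(f"network definition missing columns: {sorted(missing)}")
        bad = set(t["network"]) - set(NETWORK_IDS)
        if bad:
            raise AtlasError(f"unknown network ids: {sorted(bad)}")
        coords = t[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise AtlasError("non-finite peak coordinate in network definition")
        dup = t.duplicated(subset=["network", "label"])
        if dup.any():
            raise AtlasError(f"duplicate labels within a network: {t.loc[dup, 'label'].tolist()}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        return [n for n in NETWORK_IDS if n in set(self.table["network"])]


@dataclass
class LabelVolume:
    """Integer-labeled parcellation volume with a voxel->mm affine."""

    grid: np.ndarray
    affine: np.ndarray
    parcel_kind: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise AtlasError("label grid must be 3-D with nonzero extent")
        if not np.issubdtype(self.grid.dtype, np.integer):
            if not np.allclose(self.grid, np.round(self.grid)):
                raise AtlasError("label grid must hold integer parcel ids")
            self.grid = np.round(self.grid).astype(np.int32)
        if (self.grid < 0).any():
            raise AtlasError("parcel ids must be >= 0 (0 = background)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise AtlasError("affine must be an invertible 4x4 transform")

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        return cls(grid=data, affine=img.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.grid.astype(np.int16), self.affine), str(path))

    def mm_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Map millimetre coordinates to (fractional) voxel indices."""
        xyz_mm = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        hom = np.c_[xyz_mm, np.ones(len(xyz_mm))]
        return (hom @ inv.T)[:, :3]

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]


@dataclass
class ParcelOverlapTable:
    """Rows of (network_id, parcel_id, voxel_count), unique per pair."""

    table: pd.DataFrame  # columns: network_id, parcel_id, voxel_count

    def __post_init__(self) -> None:
        t = self.table
        required = {"network_id", "parcel_id", "voxel_count"}
        if set(t.columns) < required:
            raise AtlasError("overlap table needs network_id, parcel_id, voxel_count")
        if len(t) and (t["voxel_count"] < 1).any():
            raise AtlasError("emitted overlap rows must have voxel_count >= 1")
        if t.duplicated(subset=["network_id", "parcel_id"]).any():
            raise AtlasError("(network_id, parcel_id) pairs must be unique")


@dataclass
class NetworkParcelMap:
    """Unique parcel -> network assignment with overlap provenance."""

    assignment: dict[int, str]
    overlap: ParcelOverlapTable | None = None

    def __post_init__(self) -> None:
        _check_min_parcels(self.parcels_by_network())

    def parcels_by_network(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for pid, net in sorted(self.assignment.items()):
            out.setdefault(net, []).append(pid)
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        counts = {}
        if self.overlap is not None:
            for r in self.overlap.table.itertuples():
                counts[(r.parcel_id, r.network_id)] = r.voxel_count
        for pid, net in sorted(self.assignment.items()):
            rows.append({"parcel_id": pid, "network_id": net,
                         "voxel_count": counts.get((pid, net), -1)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NetworkParcelMap":
        t = pd.read_csv(path, sep="\t")
        assignment = dict(zip(t["parcel_id"].astype(int), t["network_id"]))
        return cls(assignment=assignment)


def _check_min_parcels(by_net: dict[str, list[int]], min_parcels: int = 2) -> None:
    for net, parcels in by_net.items():
        if len(parcels) < min_parcels:
            raise AtlasError(
                f"network {net} retains {len(parcels)} parcel(s); at least "
                f"{min_parcels} are required for within-network connectivity"
            )


def load_network_definition(path: str | Path) -> NetworkDefinition:
    """Read a TSV with columns network, label, x, y, z (MNI mm)."""
    t = pd.read_csv(path, sep="\t")
    for col in ("x", "y", "z"):
        if col in t.columns:
            t[col] = pd.to_numeric(t[col], errors="raise")
    return NetworkDefinition(table=t)


def default_network_definition() -> NetworkDefinition:
    """Packaged 36-ROI definition (synthetic coordinate stand-in)."""
    ref = resources.files("ernconn.data").joinpath("ern_rois_synthetic.tsv")
    with resources.as_file(ref) as p:
        return load_network_definition(p)


def sphere_voxels(center_mm: np.ndarray, radius_mm: float, vol: LabelVolume) -> set[tuple[int, int, int]]:
    """In-grid voxels whose centers lie within ``radius_mm`` of ``center_mm``.

    Membership uses the voxel CENTER (not any corner). Returns an empty set
    with a warning when the center lies outside the grid bounding box by more
    than the radius.
    """
    if radius_mm < 0:
        raise AtlasError("radius must be >= 0")
    center_mm = np.asarray(center_mm, dtype=float)
    ctr_vox = vol.mm_to_voxel(center_mm)[0]
    shape = np.array(vol.grid.shape)

    # conservative per-axis half-extent of the sphere in voxel units
    inv = np.linalg.inv(vol.affine)[:3, :3]
    half = radius_mm * np.linalg.norm(inv, axis=1) + 1.0
    lo = np.maximum(np.floor(ctr_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(ctr_vox + half).astype(int), shape - 1)
    if np.any(lo > hi):
        warnings.warn(f"sphere center {center_mm} lies outside the volume; empty ROI")
        return set()

    ii, jj, kk = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = vol.voxel_to_mm(ijk)
    d2 = np.sum((mm - center_mm) ** 2, axis=1)
    inside = ijk[d2 <= radius_mm**2 + 1e-9]
    if len(inside) == 0:
        warnings.warn(f"sphere at {center_mm} (r={radius_mm}) contains no voxel centers")
    return {tuple(int(v) for v in row) for row in inside}


def _resample_mask_to(vol: LabelVolume, mask_path: str | Path) -> set[tuple[int, int, int]]:
    """Nearest-neighbour resampling of a binary mask onto the label grid."""
    img = nib.load(str(mask_path))
    mask = np.asanyarray(img.dataobj) > 0
    inv = np.linalg.inv(img.affine)
    shape = vol.grid.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = vol.voxel_to_mm(ijk)
    src = (np.c_[mm, np.ones(len(mm))] @ inv.T)[:, :3]
    src = np.round(src).astype(int)
    ok = np.all((src >= 0) & (src < np.array(mask.shape)), axis=1)
    hits = ok.copy()
    hits[ok] = mask[src[ok, 0], src[ok, 1], src[ok, 2]]
    return {tuple(int(v) for v in row) for row in ijk[hits]}


def compute_overlap(
    nets: NetworkDefinition,
    vol: LabelVolume,
    mode: str = "peak",
    radius_mm: float = 6.0,
) -> ParcelOverlapTable:
    """Count ROI voxels per (network, parcel).

    In ``peak`` mode each ROI is a sphere around its peak coordinate; in
    ``cluster`` mode each ROI is its mask resampled to the label grid.
    Voxels of overlapping same-network ROIs are counted once (union).
    Background hits are logged, not emitted.
    """
    if mode not in ("peak", "cluster"):
        raise AtlasError(f"mode must be 'peak' or 'cluster', got {mode!r}")
    rows = []
    for net in nets.networks:
        sub = nets.table[nets.table["network"] == net]
        net_voxels: set[tuple[int, int, int]] = set()
        for r in sub.itertuples():
            if mode == "peak":
                vox = sphere_voxels(np.array([r.x, r.y, r.z]), radius_mm, vol)
            else:
                mask_path = getattr(r, "mask_path", None)
                if mask_path is None or (isinstance(mask_path, float) and np.isnan(mask_path)):
                    raise AtlasError(f"cluster mode requires mask_path for ROI {r.label!r}")
                vox = _resample_mask_to(vol, mask_path)
            if not vox:
                continue
            labels = {vol.grid[v] for v in vox}
            if labels == {0}:
                warnings.warn(f"ROI {r.label!r} ({net}) falls entirely in background")
            net_voxels |= vox
        if not net_voxels:
            continue
        idx = np.array(sorted(net_voxels))
        lab = vol.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        n_bg = int((lab == 0).sum())
        if n_bg:
            logger.info("%s: %d ROI voxels in background (label 0), not counted", net, n_bg)
        for pid, cnt in zip(*np.unique(lab[lab > 0], return_counts=True)):
            rows.append({"network_id": net, "parcel_id": int(pid), "voxel_count": int(cnt)})
    return ParcelOverlapTable(table=pd.DataFrame(rows, columns=["network_id", "parcel_id", "voxel_count"]))


def filter_overlap(
    table: ParcelOverlapTable,
    rule: str = "quartile",
    fixed_min: int = 5,
    per_network: bool = False,
) -> ParcelOverlapTable:
    """Drop weak (network, parcel) overlaps.

    ``quartile``: drop rows with voxel_count <= Q1 of the voxel_count
    distribution (pooled across all rows by default; linear-interpolation
    quantile convention). ``fixed``: drop rows with voxel_count <= fixed_min.
    Errors if any network would retain fewer than 2 parcels.
    """
    t = table.table
    if t.empty:
        raise AtlasError("cannot filter an empty overlap table")
    if rule == "fixed":
        keep = t[t["voxel_count"] > fixed_min]
        logger.info("fixed filter: threshold <= %d dropped %d rows", fixed_min, len(t) - len(keep))
    elif rule == "quartile":
        if per_network:
            parts = []
            for net, sub in t.groupby("network_id"):
                q1 = float(np.quantile(sub["voxel_count"], 0.25))
                parts.append(sub[sub["voxel_count"] > q1])
                logger.info("quartile filter (%s): Q1 = %.2f", net, q1)
            keep = pd.concat(parts) if parts else t.iloc[:0]
        else:
            q1 = float(np.quantile(t["voxel_count"], 0.25))
            keep = t[t["voxel_count"] > q1]
            logger.info("quartile filter (pooled): Q1 = %.2f dropped %d rows", q1, len(t) - len(keep))
    else:
        raise AtlasError(f"unknown filter rule {rule!r}")
    by_net = keep.groupby("network_id")["parcel_id"].nunique()
    for net in t["network_id"].unique():
        if by_net.get(net, 0) < 2:
            raise AtlasError(
                f"filtering leaves network {net} with {by_net.get(net, 0)} parcel(s); "
                "at least 2 are required"
            )
    return ParcelOverlapTable(table=keep.reset_index(drop=True))


def assign_parcels(table: ParcelOverlapTable) -> NetworkParcelMap:
    """Assign each parcel to the single network with the largest voxel overlap.

    Ties are broken toward the lowest network index with a warning.
    """
    t = table.table
    assignment: dict[int, str] = {}
    for pid, sub in t.groupby("parcel_id"):
        best = sub["voxel_count"].max()
        winners = sorted(sub.loc[sub["voxel_count"] == best, "network_id"])
        if len(winners) > 1:
            warnings.warn(
                f"parcel {pid}: overlap tie between {winners}; assigned to {winners[0]}"
            )
        assignment[int(pid)] = winners[0]
    won = {}
    for net in assignment.values():
        won[net] = won.get(net, 0) + 1
    _check_min_parcels({net: [0] * won.get(net, 0) for net in t["network_id"].unique()})
    return NetworkParcelMap(assignment=assignment, overlap=table)


def map_atlas(
    networks_tsv: str | Path,
    atlas_nifti: str | Path,
    mode: str = "peak",
    radius_mm: float = 6.0,
    filter_rule: str = "quartile",
    fixed_min: int = 5,
    per_network: bool = False,
) -> NetworkParcelMap:
    """Full mapping: load, overlap, filter, unique assignment."""
    nets = load_network_definition(networks_tsv)
    vol = LabelVolume.from_nifti(atlas_nifti)
    overlap = compute_overlap(nets, vol, mode=mode, radius_mm=radius_mm)
    filtered = filter_overlap(overlap, rule=filter_rule, fixed_min=fixed_min, per_network=per_network)
    return assign_parcels(filtered)
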