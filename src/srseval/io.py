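"""Volume and report I/O, run configuration, and manifests.

NRRD is the canonical on-disk volume format (explicit spacing, no affine
ambiguity); NIfTI is accepted with an axis-alignment check.  DICOM-RT
(RTDOSE / RTSTRUCT) import is read-only: RTDOSE honors DoseGridScaling,
RTSTRUCT contours are rasterized to the dose grid by point-in-polygon on
each slice.

On-disk convention: volumes are stored with array axis order (z, y, x) in
a right-handed patient frame with mm units; masks are uint8 0/1 with a
JSON sidecar ``{name, role, prescription_Gy, gtv_partner}``; dose is
float32 Gy.  Every pipeline output embeds the seed and a hash of the run
configuration so reruns are reproducible byte-for-byte (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dosimetry import DoseGrid, PlanMetrics, PolicyLimits
from .geometry import StructureMask, VoxelGrid

logger = logging.getLogger("srseval")

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "read_dicom_rtdose",
    "read_dicom_rtstruct",
    "plan_metrics_to_dict",
    "write_plan_metrics",
    "read_plan_metrics_dict",
    "plan_metrics_from_dict",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration, serialized into every manifest."""

    spacing_mm: float = 1.0
    margin_mm: float = 1.0
    merge_threshold_mm: float = 5.0
    v12_threshold_Gy: float = 12.0
    healthy_brain_reference: str = "GTV"
    min_coverage_percent: float = 98.0
    d2_warn_fraction: float = 1.30
    d2_reject_fraction: float = 1.35
    brainstem_max_Gy: float = 12.0
    optic_max_Gy: float = 8.0
    lens_max_Gy: float = 2.0
    lesion_boundary: int = 10
    gtv_threshold_cm3: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.1 <= self.spacing_mm <= 10.0:
            raise ValueError("spacing_mm must be in [0.1, 10] mm")
        if not 0.0 <= self.margin_mm <= 10.0:
            raise ValueError("margin_mm must be in [0, 10] mm")
        if not 0.0 <= self.merge_threshold_mm <= 50.0:
            raise ValueError("merge_threshold_mm must be in [0, 50] mm")
        if self.healthy_brain_reference not in ("GTV", "PTV"):
            raise ValueError("healthy_brain_reference must be 'GTV' or 'PTV'")
        if not 0.0 < self.min_coverage_percent <= 100.0:
            raise ValueError("min_coverage_percent must be in (0, 100]")
        if not 1.0 < self.d2_warn_fraction <= self.d2_reject_fraction:
            raise ValueError("need 1 < d2_warn_fraction <= d2_reject_fraction")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def policy_limits(self) -> PolicyLimits:
        return PolicyLimits(
            min_coverage_percent=self.min_coverage_percent,
            d2_warn_fraction=self.d2_warn_fraction,
            d2_reject_fraction=self.d2_reject_fraction,
            oar_max_Gy=(
                ("brainstem", self.brainstem_max_Gy),
                ("optic_apparatus", self.optic_max_Gy),
                ("lens", self.lens_max_Gy),
            ),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# --------------------------------------------------------------------------
# volumes (NRRD / NIfTI via SimpleITK, NIfTI alignment-checked)
# --------------------------------------------------------------------------

def _sitk():
    import SimpleITK as sitk

    return sitk


def _grid_from_sitk(img) -> VoxelGrid:
    # SimpleITK metadata is (x, y, z); arrays come back (z, y, x)
    sp = tuple(reversed(img.GetSpacing()))
    og = tuple(reversed(img.GetOrigin()))
    size = tuple(reversed(img.GetSize()))
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "only axis-aligned volumes are supported (direction must be identity)"
        )
    return VoxelGrid(shape=size, spacing_mm=sp, origin_mm=og)


def read_volume(path: str | Path, kind: str = "dose") -> DoseGrid | np.ndarray:
    """Read an NRRD or NIfTI volume.

    ``kind="dose"`` returns a :class:`DoseGrid` in Gy; ``kind="mask"``
    returns ``(VoxelGrid, bool array)`` — use :func:`read_mask` to get a
    full :class:`StructureMask` with its sidecar metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if kind not in ("dose", "mask"):
        raise ValueError("kind must be 'dose' or 'mask'")
    sitk = _sitk()
    img = sitk.ReadImage(str(path))
    grid = _grid_from_sitk(img)
    arr = sitk.GetArrayFromImage(img)
    if kind == "dose":
        return DoseGrid(grid, arr.astype(np.float64))
    return grid, arr.astype(bool)


def write_volume(
    path: str | Path, grid: VoxelGrid, array: np.ndarray
) -> None:
    """Write a volume as NRRD or NIfTI (by extension), axis order (z,y,x)."""
    sitk = _sitk()
    img = sitk.GetImageFromArray(np.ascontiguousarray(array))
    img.SetSpacing(tuple(reversed(grid.spacing_mm)))
    img.SetOrigin(tuple(reversed(grid.origin_mm)))
    sitk.WriteImage(img, str(path), useCompression=True)


def write_mask(path: str | Path, mask: StructureMask,
               prescription_Gy: float | None = None,
               gtv_partner: str | None = None) -> None:
    """Write a mask (uint8 0/1) plus its JSON sidecar."""
    path = Path(path)
    write_volume(path, mask.grid, mask.voxels.astype(np.uint8))
    sidecar = {
        "name": mask.name,
        "role": mask.role,
        "prescription_Gy": prescription_Gy,
        "gtv_partner": gtv_partner,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_mask(path: str | Path) -> tuple[StructureMask, dict]:
    """Read a mask volume and its JSON sidecar."""
    path = Path(path)
    grid, vox = read_volume(path, kind="mask")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"mask sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    mask = StructureMask(name=meta["name"], role=meta["role"], grid=grid, voxels=vox)
    return mask, meta


# --------------------------------------------------------------------------
# DICOM-RT import (read-only)
# --------------------------------------------------------------------------

def read_dicom_rtdose(path: str | Path) -> DoseGrid:
    """Import an RTDOSE file; dose in Gy = stored values × DoseGridScaling."""
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RTDOSE file not found: {path}")
    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(np.float64) * scaling
    dz = None
    offsets = getattr(ds, "GridFrameOffsetVector", None)
    if offsets is not None and len(offsets) > 1:
        steps = np.diff(np.asarray(offsets, dtype=float))
        if not np.allclose(steps, steps[0]):
            raise ValueError("non-uniform GridFrameOffsetVector is unsupported")
        dz = abs(float(steps[0]))
    if dz is None:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    ipp = [float(v) for v in ds.ImagePositionPatient]
    grid = VoxelGrid(
        shape=arr.shape,
        spacing_mm=(dz, dy, dx),
        # ImagePositionPatient addresses the first voxel *center*
        origin_mm=(ipp[2] - dz / 2, ipp[1] - dy / 2, ipp[0] - dx / 2),
    )
    return DoseGrid(grid, arr)


def read_dicom_rtstruct(
    path: str | Path, grid: VoxelGrid, roles: dict[str, str] | None = None
) -> list[StructureMask]:
    """Rasterize RTSTRUCT contours to a voxel grid.

    Each planar contour is filled by point-in-polygon over the voxel
    centers of its slice; slices stack along z.  ``roles`` maps structure
    names to anatomical roles (default "derived").
    """
    import pydicom
    from matplotlib.path import Path as MplPath

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RTSTRUCT file not found: {path}")
    ds = pydicom.dcmread(str(path))
    roles = roles or {}
    names = {
        int(r.ROINumber): r.ROIName for r in ds.StructureSetROISequence
    }
    yc = grid.axis_centers_mm(1)
    xc = grid.axis_centers_mm(2)
    xx, yy = np.meshgrid(xc, yc)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    zc = grid.axis_centers_mm(0)

    masks = []
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), f"ROI{roi.ReferencedROINumber}")
        vox = np.zeros(grid.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = data[:, 2].mean()
            iz = int(np.argmin(np.abs(zc - z)))
            poly = MplPath(data[:, :2])  # (x, y)
            inside = poly.contains_points(pts).reshape(len(yc), len(xc))
            vox[iz] |= inside
        masks.append(
            StructureMask(name=name, role=roles.get(name, "derived"), grid=grid, voxels=vox)
        )
    return masks


# --------------------------------------------------------------------------
# metrics serialization
# --------------------------------------------------------------------------

def plan_metrics_to_dict(m: PlanMetrics) -> dict:
    d = m.as_flat_dict()
    d["targets"] = [
        {
            "name": t.name,
            "prescription_Gy": t.prescription_Gy,
            "coverage_percent": t.coverage_percent,
            "ci": t.ci,
            "d2_percent_Gy": t.d2_percent_Gy,
            "mean_Gy": t.mean_Gy,
            "v_pi_cm3": t.v_pi_cm3,
            "v_pi_ptv_cm3": t.v_pi_ptv_cm3,
            "v_ptv_cm3": t.v_ptv_cm3,
        }
        for t in m.targets
    ]
    d["v12_clusters"] = [
        {"volume_cm3": c.volume_cm3, "gtv_names": list(c.gtv_names)}
        for c in m.v12_clusters
    ]
    if m.policy_result is not None:
        d["policy_reasons"] = m.policy_result.reasons
    return d


def write_plan_metrics(path: str | Path, m: PlanMetrics, manifest: dict) -> None:
    payload = {"manifest": manifest, "metrics": plan_metrics_to_dict(m)}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_plan_metrics_dict(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def plan_metrics_from_dict(d: dict) -> PlanMetrics:
    """Rebuild a :class:`PlanMetrics` from its JSON form."""
    from .dosimetry import PolicyResult, TargetMetrics, V12Cluster

    targets = [TargetMetrics(**t) for t in d["targets"]]
    clusters = [
        V12Cluster(volume_cm3=c["volume_cm3"], gtv_names=tuple(c["gtv_names"]))
        for c in d.get("v12_clusters", [])
    ]
    policy = None
    if "policy_status" in d:
        policy = PolicyResult(d["policy_status"], d.get("policy_reasons", []))
    oar_max = {
        k.removeprefix("max_").removesuffix("_Gy"): v
        for k, v in d.items()
        if k.startswith("max_") and k.endswith("_Gy")
    }
    return PlanMetrics(
        targets=targets,
        ci=d["ci"],
        gi=d["gi"],
        coverage_percent=d["coverage_percent"],
        ptv_mean_Gy=d["ptv_mean_Gy"],
        d2_cumulative_Gy=d["d2_cumulative_Gy"],
        brain_mean_Gy=d["brain_mean_Gy"],
        v5_cm3=d["v5_cm3"],
        v8_cm3=d["v8_cm3"],
        v10_cm3=d["v10_cm3"],
        v12_cm3=d["v12_cm3"],
        v12_clusters=clusters,
        hippocampus_L_mean_Gy=d.get("hippocampus_L_mean_Gy"),
        hippocampus_R_mean_Gy=d.get("hippocampus_R_mean_Gy"),
        oar_max_Gy=oar_max,
        reference_prescription_Gy=d["reference_prescription_Gy"],
        policy_result=policy,
    )
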