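"""DVH computation, dosimetric indices and plan-acceptance policy for SRS.

All volume metrics use voxel-center membership and a closed dose threshold
(``dose >= X``): for the continuous dose fields that clinical systems
produce the boundary set has measure zero, and the closed convention keeps
``cumulative_dvh`` and ``volume_at_dose`` exactly consistent at bin edges.

Key quantities
--------------
* Paddick conformity index ``CI = (V_PI,PTV / V_PTV) * (V_PI,PTV / V_PI)``
  where ``V_PI`` is the volume covered by 100% of the prescription dose.
  CI = 1 is ideal conformity.
* Gradient index ``GI = V_50% / V_PI`` — ratio of the half-prescription
  isodose volume to the prescription isodose volume; lower is a steeper
  falloff, with 1 the idealized limit.
* ``V_xGy`` — absolute healthy-brain (brain − GTV) volume receiving at
  least x Gy; V12Gy is the standard radionecrosis-risk surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    StructureMask,
    StructureSet,
    VoxelGrid,
    connected_components,
    merge_close_structures,
    union,
)

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "TargetMetrics",
    "V12Cluster",
    "PolicyResult",
    "PlanMetrics",
    "PolicyLimits",
    "cumulative_dvh",
    "volume_at_dose",
    "dose_at_volume_fraction",
    "mean_dose",
    "max_dose",
    "coverage_percent",
    "paddick_ci",
    "gradient_index",
    "v12_cluster_volumes",
    "evaluate_plan",
    "check_policy",
]


@dataclass
class DoseGrid:
    """A 3D absorbed-dose field in Gy on a regular voxel grid."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose)
        if self.dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.dose.shape} does not match grid {self.grid.shape}"
            )
        if not np.isfinite(self.dose).all():
            raise ValueError("dose must be finite everywhere")
        if (self.dose < 0).any():
            raise ValueError("dose must be non-negative")

    @property
    def max_Gy(self) -> float:
        return float(self.dose.max())


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    structure_name: str
    dose_bins_Gy: np.ndarray
    cumulative_volume_cm3: np.ndarray

    def volume_at(self, dose_Gy: float) -> float:
        """Volume receiving at least ``dose_Gy`` (step interpolation)."""
        idx = np.searchsorted(self.dose_bins_Gy, dose_Gy, side="right") - 1
        if idx < 0:
            return float(self.cumulative_volume_cm3[0])
        return float(self.cumulative_volume_cm3[idx])


@dataclass
class TargetMetrics:
    """Per-target dosimetric outputs."""

    name: str
    prescription_Gy: float
    coverage_percent: float
    ci: float
    d2_percent_Gy: float
    mean_Gy: float
    v_pi_cm3: float
    v_pi_ptv_cm3: float
    v_ptv_cm3: float
    gi: float | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.coverage_percent <= 100.0
        assert -1e-12 <= self.ci <= 1.0 + 1e-12
        assert self.v_pi_ptv_cm3 <= min(self.v_pi_cm3, self.v_ptv_cm3) + 1e-9


@dataclass
class V12Cluster:
    """One connected supra-threshold healthy-brain component."""

    volume_cm3: float
    gtv_names: tuple[str, ...]

    @property
    def is_merged(self) -> bool:
        return len(self.gtv_names) > 1


@dataclass
class PolicyResult:
    status: str  # "pass" | "warn" | "fail"
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status != "fail"


@dataclass
class PlanMetrics:
    """All per-plan dosimetric outputs assembled by :func:`evaluate_plan`."""

    targets: list[TargetMetrics]
    ci: float
    gi: float
    coverage_percent: float
    ptv_mean_Gy: float
    d2_cumulative_Gy: float
    brain_mean_Gy: float
    v5_cm3: float
    v8_cm3: float
    v10_cm3: float
    v12_cm3: float
    v12_clusters: list[V12Cluster]
    hippocampus_L_mean_Gy: float | None
    hippocampus_R_mean_Gy: float | None
    oar_max_Gy: dict[str, float]
    reference_prescription_Gy: float
    policy_result: PolicyResult | None = None

    def as_flat_dict(self) -> dict:
        d = {
            "ci": self.ci,
            "gi": self.gi,
            "coverage_percent": self.coverage_percent,
            "ptv_mean_Gy": self.ptv_mean_Gy,
            "d2_cumulative_Gy": self.d2_cumulative_Gy,
            "brain_mean_Gy": self.brain_mean_Gy,
            "v5_cm3": self.v5_cm3,
            "v8_cm3": self.v8_cm3,
            "v10_cm3": self.v10_cm3,
            "v12_cm3": self.v12_cm3,
            "hippocampus_L_mean_Gy": self.hippocampus_L_mean_Gy,
            "hippocampus_R_mean_Gy": self.hippocampus_R_mean_Gy,
            "reference_prescription_Gy": self.reference_prescription_Gy,
        }
        for name, v in self.oar_max_Gy.items():
            d[f"max_{name}_Gy"] = v
        if self.policy_result is not None:
            d["policy_status"] = self.policy_result.status
        return d


@dataclass(frozen=True)
class PolicyLimits:
    """Clinical plan-acceptance limits.

    Defaults follow a single-fraction SIMT SRS policy: every PTV covered by
    the prescription dose over at least 98% of its volume; per-PTV hotspot
    D2% below 130% of the prescription (warning tier); cumulative-PTV D2%
    above 135% of the prescription rejected; organ-at-risk maxima of 12 Gy
    (brainstem), 8 Gy (optic apparatus) and 2 Gy (lens).
    """

    min_coverage_percent: float = 98.0
    d2_warn_fraction: float = 1.30
    d2_reject_fraction: float = 1.35
    oar_max_Gy: tuple[tuple[str, float], ...] = (
        ("brainstem", 12.0),
        ("optic_apparatus", 8.0),
        ("lens", 2.0),
    )


def _require_same_grid(dose: DoseGrid, mask: StructureMask) -> None:
    if dose.grid != mask.grid:
        raise ValueError(f"dose and mask {mask.name!r} are on different grids")


def _mask_values(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    """Dose values inside a mask, extracted on the mask bounding box."""
    box = mask.bbox
    if box is None:
        return np.empty(0, dtype=dose.dose.dtype)
    return dose.dose[box][mask.voxels[box]]


def cumulative_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width_Gy: float = 0.1
) -> DVHCurve:
    """Cumulative DVH: bin b holds the volume receiving >= b Gy."""
    _require_same_grid(dose, mask)
    if bin_width_Gy <= 0:
        raise ValueError(f"bin_width_Gy must be positive, got {bin_width_Gy}")
    if mask.is_empty:
        raise ValueError(f"cannot compute DVH of empty mask {mask.name!r}")
    vals = np.sort(_mask_values(dose, mask).astype(float))
    top = vals[-1]
    edges = np.arange(0.0, top + 2 * bin_width_Gy, bin_width_Gy)
    # voxels with dose >= edge == total - (count of dose < edge)
    below = np.searchsorted(vals, edges, side="left")
    vol = (vals.size - below) * mask.grid.voxel_volume_cm3
    return DVHCurve(mask.name, edges, vol)


def volume_at_dose(dose: DoseGrid, mask: StructureMask, threshold_Gy: float) -> float:
    """Volume (cm³) of mask voxels with dose >= threshold."""
    _require_same_grid(dose, mask)
    n = int(np.count_nonzero(_mask_values(dose, mask) >= threshold_Gy))
    return n * mask.grid.voxel_volume_cm3


def dose_at_volume_fraction(
    dose: DoseGrid, mask: StructureMask, fraction: float
) -> float:
    """Largest dose d such that at least ``fraction`` of the mask gets >= d.

    D2% is ``fraction=0.02``; ``fraction=1.0`` returns the minimum dose.
    Computed by exact voxel sorting (grid-exact, no DVH interpolation).
    """
    _require_same_grid(dose, mask)
    if mask.is_empty:
        raise ValueError(f"cannot compute dose-at-volume of empty mask {mask.name!r}")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    vals = np.sort(_mask_values(dose, mask).astype(float))[::-1]
    k = int(np.ceil(fraction * vals.size))
    return float(vals[k - 1])


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    _require_same_grid(dose, mask)
    if mask.is_empty:
        raise ValueError(f"cannot compute mean dose of empty mask {mask.name!r}")
    return float(_mask_values(dose, mask).mean())


def max_dose(dose: DoseGrid, mask: StructureMask) -> float:
    _require_same_grid(dose, mask)
    if mask.is_empty:
        raise ValueError(f"cannot compute max dose of empty mask {mask.name!r}")
    return float(_mask_values(dose, mask).max())


def coverage_percent(dose: DoseGrid, ptv: StructureMask, pd_Gy: float) -> float:
    """Percent of the PTV receiving at least the prescription dose."""
    _require_same_grid(dose, ptv)
    if ptv.is_empty:
        raise ValueError(f"cannot compute coverage of empty PTV {ptv.name!r}")
    covered = int(np.count_nonzero(_mask_values(dose, ptv) >= pd_Gy))
    return 100.0 * covered / ptv.voxel_count


def paddick_ci(
    dose: DoseGrid,
    ptv: StructureMask,
    pd_Gy: float,
    isodose_region: StructureMask | None = None,
) -> float:
    """Paddick conformity index.

    ``CI = (V_PI,PTV / V_PTV) * (V_PI,PTV / V_PI)`` — the product of target
    coverage fraction and selectivity.  ``V_PI`` defaults to the whole-grid
    prescription isodose volume; pass ``isodose_region`` to restrict it
    (e.g. to the part of the grid attributed to one target of a
    multi-target plan).
    """
    _require_same_grid(dose, ptv)
    if ptv.is_empty:
        raise ValueError(f"cannot compute CI of empty PTV {ptv.name!r}")
    supra = dose.dose >= pd_Gy
    if isodose_region is not None:
        supra = supra & isodose_region.voxels
    v_pi = int(supra.sum())
    if v_pi == 0:
        warnings.warn(
            f"no voxel reaches the prescription dose {pd_Gy} Gy; CI defined as 0",
            stacklevel=2,
        )
        return 0.0
    v_pi_ptv = int(np.count_nonzero(supra & ptv.voxels))
    v_ptv = ptv.voxel_count
    return (v_pi_ptv / v_ptv) * (v_pi_ptv / v_pi)


def gradient_index(dose: DoseGrid, pd_Gy: float) -> float:
    """Gradient index GI = V_50% / V_PI over the whole grid."""
    if pd_Gy <= 0:
        raise ValueError(f"prescription dose must be positive, got {pd_Gy}")
    v_pi = int(np.count_nonzero(dose.dose >= pd_Gy))
    if v_pi == 0:
        raise ValueError(
            f"no voxel reaches the prescription dose {pd_Gy} Gy; GI undefined"
        )
    v_50 = int(np.count_nonzero(dose.dose >= 0.5 * pd_Gy))
    return v_50 / v_pi


def v12_cluster_volumes(
    dose: DoseGrid,
    brain: StructureMask,
    gtvs: list[StructureMask],
    threshold_Gy: float = 12.0,
    connectivity: int = 26,
) -> list[V12Cluster]:
    """Partition healthy-brain supra-threshold volume into clusters.

    The 12 Gy shells that form around each lesion are labelled on the full
    supra-threshold region (including target interiors, so a shell and the
    lesion that produces it connect), then each connected component is
    reported as the healthy-brain (brain − GTV) volume it contains,
    tagged with every GTV it touches.  Shells of adjacent lesions that
    bridge are reported as a single merged cluster carrying all their GTV
    names.  Cluster volumes always sum to the total healthy-brain
    ``V_threshold`` exactly (partition property).
    """
    _require_same_grid(dose, brain)
    for g in gtvs:
        _require_same_grid(dose, g)
    supra = dose.dose >= threshold_Gy
    if not supra.any():
        return []
    labels, n = connected_components(
        StructureMask("supra", "derived", dose.grid, supra), connectivity
    )
    healthy = brain.voxels.copy()
    for g in gtvs:
        healthy &= ~g.voxels

    vv = dose.grid.voxel_volume_cm3
    counts = np.bincount(labels[healthy & supra].ravel(), minlength=n + 1)
    touched: dict[int, list[str]] = {}
    for g in gtvs:
        box = g.bbox
        if box is None:
            continue
        for lab in np.unique(labels[box][g.voxels[box]]):
            if lab:
                touched.setdefault(int(lab), []).append(g.name)
    clusters: list[V12Cluster] = []
    for lab in range(1, n + 1):
        names = tuple(touched.get(lab, ()))
        vol = float(counts[lab]) * vv
        if vol > 0 or names:
            clusters.append(V12Cluster(volume_cm3=vol, gtv_names=names))
    return clusters


def _nearest_target_assignment(
    grid: VoxelGrid, voxel_idx: tuple[np.ndarray, ...], centroids_mm: np.ndarray
) -> np.ndarray:
    """Index of the nearest target centroid for a set of voxels."""
    coords = [
        grid.origin_mm[ax] + (voxel_idx[ax] + 0.5) * grid.spacing_mm[ax]
        for ax in range(3)
    ]
    n = coords[0].size
    best = np.zeros(n, dtype=np.int32)
    best_d2 = np.full(n, np.inf)
    for t, c in enumerate(centroids_mm):
        d2 = (coords[0] - c[0]) ** 2
        d2 += (coords[1] - c[1]) ** 2
        d2 += (coords[2] - c[2]) ** 2
        upd = d2 < best_d2
        best[upd] = t
        best_d2[upd] = d2[upd]
    return best


def evaluate_plan(
    dose: DoseGrid,
    structures: StructureSet,
    prescriptions: dict[str, float],
    merge_threshold_mm: float | None = 5.0,
    healthy_brain_reference: str = "GTV",
    policy: PolicyLimits | None = PolicyLimits(),
    v12_threshold_Gy: float = 12.0,
) -> PlanMetrics:
    """Compute every per-plan dosimetric metric.

    Parameters
    ----------
    prescriptions
        Prescription dose (Gy) per PTV name.
    merge_threshold_mm
        PTVs with surface distance below this are merged and evaluated as
        one target (None disables).  A merged target takes the maximum
        member prescription.
    healthy_brain_reference
        "GTV" (default) evaluates V_xGy on brain − GTV; "PTV" on
        brain − PTV.

    When prescriptions differ across targets, each voxel is attributed to
    its nearest target (by PTV centroid) and the local prescription is
    used for the V_PI / V_50% thresholds; with a uniform prescription this
    reduces to plain global thresholds.
    """
    ptvs = structures.ptvs
    if not ptvs:
        raise ValueError("structure set contains no PTV")
    missing = [p.name for p in ptvs if p.name not in prescriptions]
    if missing:
        raise ValueError(f"no prescription for PTVs: {missing}")

    # --- merged-target rule -------------------------------------------------
    if merge_threshold_mm is not None and len(ptvs) > 1:
        merged = merge_close_structures(ptvs, merge_threshold_mm)
    else:
        merged = list(ptvs)
    merged_pd = {
        m.name: max(prescriptions[n] for n in m.name.split("+")) for m in merged
    }

    grid = dose.grid
    vv = grid.voxel_volume_cm3
    pds = np.array([merged_pd[m.name] for m in merged])
    ref_pd = float(pds.max())

    # --- per-voxel local prescription (nearest-target attribution) ----------
    # With several targets each voxel is attributed to the nearest target
    # centroid, so per-target selectivity is judged against that target's
    # own share of the isodose and (for mixed 18/20 Gy plans) against the
    # local prescription.  For uniform prescriptions the attribution does
    # not change the global V_PI / V_50%.
    if len(merged) == 1:
        supra_pi = dose.dose >= pds[0]
        supra_50 = dose.dose >= 0.5 * pds[0]
        assign_of = None
    else:
        centroids = np.stack([m.centroid_mm() for m in merged])
        cand = dose.dose >= 0.5 * pds.min()
        idx = np.nonzero(cand)
        assign = _nearest_target_assignment(grid, idx, centroids)
        local_pd = pds[assign]
        vals = dose.dose[idx]
        supra_pi = np.zeros(grid.shape, dtype=bool)
        supra_pi[idx] = vals >= local_pd
        supra_50 = np.zeros(grid.shape, dtype=bool)
        supra_50[idx] = vals >= 0.5 * local_pd
        assign_of = np.full(grid.shape, -1, dtype=np.int32)
        assign_of[idx] = assign

    v_pi_total = int(supra_pi.sum())
    v50_total = int(supra_50.sum())
    if v_pi_total == 0:
        raise ValueError("no voxel reaches the prescription dose; plan is degenerate")
    gi_global = v50_total / v_pi_total

    # --- per-target metrics -------------------------------------------------
    target_metrics: list[TargetMetrics] = []
    for ti, m in enumerate(merged):
        pd_t = merged_pd[m.name]
        cov = coverage_percent(dose, m, pd_t)
        d2 = dose_at_volume_fraction(dose, m, 0.02)
        mean_t = mean_dose(dose, m)
        if assign_of is None:
            region = supra_pi
        else:
            region = supra_pi & (assign_of == ti)
        v_pi_t = int(region.sum())
        v_pi_ptv = int(np.count_nonzero(region & m.voxels))
        v_ptv = m.voxel_count
        if v_pi_t == 0:
            ci_t = 0.0
        else:
            ci_t = (v_pi_ptv / v_ptv) * (v_pi_ptv / v_pi_t)
        # per-target CI uses the target-attributed isodose; with one target
        # (or uniform PD and a single merged target) it equals the plain CI
        target_metrics.append(
            TargetMetrics(
                name=m.name,
                prescription_Gy=pd_t,
                coverage_percent=cov,
                ci=min(ci_t, 1.0),
                d2_percent_Gy=d2,
                mean_Gy=mean_t,
                v_pi_cm3=v_pi_t * vv,
                v_pi_ptv_cm3=v_pi_ptv * vv,
                v_ptv_cm3=v_ptv * vv,
            )
        )

    # plan-level CI: volume-weighted mean of per-target CI.  For uniform-PD
    # plans the per-target CIs share the global V_PI, so the weighting only
    # matters when targets differ in size.
    w = np.array([t.v_ptv_cm3 for t in target_metrics])
    ci_plan = float(np.average([t.ci for t in target_metrics], weights=w))
    cov_plan = float(np.average([t.coverage_percent for t in target_metrics], weights=w))

    # --- healthy brain ------------------------------------------------------
    brain = structures.brain
    gtvs = structures.gtvs
    if healthy_brain_reference == "GTV":
        ref_masks = gtvs if gtvs else list(ptvs)
    elif healthy_brain_reference == "PTV":
        ref_masks = list(ptvs)
    else:
        raise ValueError("healthy_brain_reference must be 'GTV' or 'PTV'")
    healthy_vox = brain.voxels.copy()
    for g in ref_masks:
        healthy_vox &= ~g.voxels
    healthy = StructureMask("healthy_brain", "derived", grid, healthy_vox)

    hb_dose = dose.dose[healthy.voxels]
    brain_mean = float(hb_dose.mean()) if hb_dose.size else 0.0
    v_of = lambda thr: int(np.count_nonzero(hb_dose >= thr)) * vv
    v5, v8, v10, v12 = v_of(5.0), v_of(8.0), v_of(10.0), v_of(v12_threshold_Gy)

    clusters = v12_cluster_volumes(
        dose, brain, ref_masks, threshold_Gy=v12_threshold_Gy
    )

    # --- PTV composite ------------------------------------------------------
    all_ptv = union(list(ptvs), name="PTV_all")
    d2_cum = dose_at_volume_fraction(dose, all_ptv, 0.02)
    ptv_mean = mean_dose(dose, all_ptv)

    # --- OARs ---------------------------------------------------------------
    def _mean_or_none(role: str) -> float | None:
        ms = structures.by_role(role)
        if not ms or all(m.is_empty for m in ms):
            return None
        return mean_dose(dose, union(ms, name=role))

    oar_max: dict[str, float] = {}
    for role in ("brainstem", "optic_apparatus", "lens"):
        ms = [m for m in structures.by_role(role) if not m.is_empty]
        if ms:
            oar_max[role] = max(max_dose(dose, m) for m in ms)

    metrics = PlanMetrics(
        targets=target_metrics,
        ci=ci_plan,
        gi=gi_global,
        coverage_percent=cov_plan,
        ptv_mean_Gy=ptv_mean,
        d2_cumulative_Gy=d2_cum,
        brain_mean_Gy=brain_mean,
        v5_cm3=v5,
        v8_cm3=v8,
        v10_cm3=v10,
        v12_cm3=v12,
        v12_clusters=clusters,
        hippocampus_L_mean_Gy=_mean_or_none("hippocampus_L"),
        hippocampus_R_mean_Gy=_mean_or_none("hippocampus_R"),
        oar_max_Gy=oar_max,
        reference_prescription_Gy=ref_pd,
    )
    if policy is not None:
        metrics.policy_result = check_policy(metrics, policy)
    return metrics


def check_policy(metrics: PlanMetrics, limits: PolicyLimits = PolicyLimits()) -> PolicyResult:
    """Apply the plan-acceptance policy to computed metrics.

    Rules: every PTV covered >= 98%; per-PTV D2% < 130% of its prescription
    (violation is a warning, mirroring the two-tier clinical rule);
    cumulative-PTV D2% > 135% of the reference prescription is a rejection;
    organ-at-risk maxima are hard limits.
    """
    reasons: list[str] = []
    warn = False
    for t in metrics.targets:
        if t.coverage_percent < limits.min_coverage_percent:
            reasons.append(
                f"coverage of {t.name} is {t.coverage_percent:.1f}% "
                f"(< {limits.min_coverage_percent:.0f}%)"
            )
        if t.d2_percent_Gy >= limits.d2_warn_fraction * t.prescription_Gy:
            warn = True
    d2_limit = limits.d2_reject_fraction * metrics.reference_prescription_Gy
    if metrics.d2_cumulative_Gy > d2_limit:
        reasons.append(
            f"cumulative PTV D2% = {metrics.d2_cumulative_Gy:.1f} Gy exceeds "
            f"{limits.d2_reject_fraction:.0%} of prescription ({d2_limit:.1f} Gy)"
        )
    for role, lim in limits.oar_max_Gy:
        got = metrics.oar_max_Gy.get(role)
        if got is not None and got > lim:
            reasons.append(f"{role} max dose {got:.1f} Gy exceeds {lim:.0f} Gy")
    if reasons:
        return PolicyResult("fail", reasons)
    if warn:
        return PolicyResult(
            "warn", ["a PTV D2% is at or above 130% of its prescription"]
        )
    return PolicyResult("pass", [])
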