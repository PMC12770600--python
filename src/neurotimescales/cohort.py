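"""Synthetic longitudinal ROI-timeseries cohort with known timescale structure.

Emulates a longitudinal stroke study design: 15 controls scanned once and
15 patients scanned five times (~monthly), 32 ROIs grouped into 8 canonical
resting-state networks, TR = 2 s, 210 acquired volumes of which the first
10 are dummy scans, leaving 200 analysed timepoints.

Each ROI series is a stationary AR(1) process whose coefficient φ is set
per (network, group, outcome, session).  AR(1) is the generative family
because its theoretical autocorrelation is the closed form φ^k, which makes
every downstream timescale metric's expected behaviour derivable: INT is
strictly increasing in φ, so designed group differences in φ translate into
designed INT effects.

Ground-truth structure encoded by the defaults:

* controls carry a strictly monotone INT hierarchy over the network order
  CE < VIS < SMN < SAN < DAN < FPN < LN < DMN (cerebellar shortest,
  default-mode longest);
* patients at session 1 have globally elevated φ with the hierarchy
  reversed (largest elevation in CE), so patient INT exceeds control INT in
  every network and the network ordering anticorrelates with the controls';
* good-outcome patients (6 of 15) decay toward — but never reach — control
  levels across sessions 2-5; poor-outcome patients stay elevated, with the
  largest good/poor separation at session 2.

Head-motion tables (6 rigid-body parameters per frame) are drawn as small
random walks so framewise displacement stays far below exclusion
thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .timescales import TimeSeries

__all__ = [
    "NETWORKS",
    "MOTION_COLUMNS",
    "Parcellation",
    "CohortSpec",
    "CohortSpecError",
    "RoiTimeSeries",
    "SubjectScan",
    "default_parcellation",
    "ar1_series",
    "generate_motion",
    "framewise_displacement",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

#: Network labels in the control-hierarchy order (shortest to longest INT).
NETWORKS = ("CE", "VIS", "SMN", "SAN", "DAN", "FPN", "LN", "DMN")

MOTION_COLUMNS = ("dx_mm", "dy_mm", "dz_mm", "alpha_deg", "beta_deg", "gamma_deg")

_CONTROL_PHI = dict(zip(NETWORKS, (0.15, 0.22, 0.29, 0.36, 0.43, 0.50, 0.57, 0.64)))
_PATIENT1_PHI = dict(
    zip(NETWORKS, (0.930, 0.915, 0.900, 0.885, 0.870, 0.855, 0.840, 0.825))
)
# Fraction of the session-1 elevation (over control) retained per session.
_GOOD_PROFILE = {1: 1.00, 2: 0.40, 3: 0.32, 4: 0.27, 5: 0.22}
_POOR_PROFILE = {1: 1.00, 2: 0.88, 3: 0.84, 4: 0.80, 5: 0.76}


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its design invariants."""


@dataclass(frozen=True)
class Parcellation:
    """32 ROI labels mapped onto the 8 functional networks."""

    roi_names: tuple[str, ...]
    network_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(set(self.roi_names)):
            raise ValueError("ROI names must be unique")
        missing = [r for r in self.roi_names if r not in self.network_of]
        if missing:
            raise ValueError(f"ROIs without a network: {missing}")
        present = set(self.network_of[r] for r in self.roi_names)
        if not present == set(NETWORKS):
            raise ValueError(f"all 8 networks must be non-empty, got {sorted(present)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)


def default_parcellation(rois_per_network: int = 4) -> Parcellation:
    """32-ROI parcellation: ``rois_per_network`` ROIs per network,
    labelled e.g. CE1..CE4."""
    names: list[str] = []
    network_of: dict[str, str] = {}
    for net in NETWORKS:
        for i in range(rois_per_network):
            name = f"{net}{i + 1}"
            names.append(name)
            network_of[name] = net
    return Parcellation(roi_names=tuple(names), network_of=network_of)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: sizes, scan geometry and per-network AR(1) coefficients.

    ``n_timepoints`` is derived: acquired volumes minus discarded dummy
    volumes (210 - 10 = 200 by default).
    """

    n_controls: int = 15
    n_patients: int = 15
    n_good: int = 6
    n_sessions_patients: int = 5
    n_volumes: int = 210
    n_dummy_volumes: int = 10
    tr: float = 2.0
    control_phi: dict[str, float] = field(default_factory=lambda: dict(_CONTROL_PHI))
    patient1_phi: dict[str, float] = field(default_factory=lambda: dict(_PATIENT1_PHI))
    good_profile: dict[int, float] = field(default_factory=lambda: dict(_GOOD_PROFILE))
    poor_profile: dict[int, float] = field(default_factory=lambda: dict(_POOR_PROFILE))
    noise_sd: float = 1.0
    network_noise_sd: float = 0.0
    seed: int = 0

    @property
    def n_timepoints(self) -> int:
        return self.n_volumes - self.n_dummy_volumes

    def phi_for(self, group: str, outcome: str, session: int, network: str) -> float:
        """AR(1) coefficient for one (group, outcome, session, network) cell."""
        ctr = self.control_phi[network]
        if group == "control":
            return ctr
        profile = self.good_profile if outcome == "good" else self.poor_profile
        return ctr + (self.patient1_phi[network] - ctr) * profile[session]

    def validate(self) -> None:
        """Check the design invariants; raise listing every violation."""
        problems: list[str] = []
        if self.n_dummy_volumes >= self.n_volumes:
            problems.append("dummy volumes must be fewer than acquired volumes")
        if not 0 <= self.n_good <= self.n_patients:
            problems.append("n_good must be in [0, n_patients]")
        phis = list(self.control_phi.values()) + list(self.patient1_phi.values())
        if any(not 0.0 <= p < 1.0 for p in phis):
            problems.append("all phi must be in [0, 1)")
        ordered = [self.control_phi[n] for n in NETWORKS]
        if not all(a < b for a, b in zip(ordered, ordered[1:])):
            problems.append(
                "control phi must increase strictly over the network order "
                + " < ".join(NETWORKS)
            )
        for net in NETWORKS:
            if self.patient1_phi[net] < self.control_phi[net]:
                problems.append(f"patient session-1 phi below control in {net}")
        for net in ("SAN", "DAN", "LN"):
            if not self.phi_for("patient", "poor", 2, net) > self.phi_for(
                "patient", "good", 2, net
            ):
                problems.append(f"poor phi must exceed good phi at session 2 in {net}")
        if problems:
            raise CohortSpecError("; ".join(problems))


@dataclass(frozen=True)
class RoiTimeSeries:
    """One scan's timepoints x ROI matrix with its TR and parcellation."""

    data: pd.DataFrame
    tr: float
    parcellation: Parcellation

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.parcellation.roi_names):
            raise ValueError("data columns must match parcellation ROI names")

    def series(self, roi: str) -> TimeSeries:
        return TimeSeries(self.data[roi].to_numpy(), dt=self.tr, label=roi)


@dataclass(frozen=True)
class SubjectScan:
    subject_id: str
    group: str  # control | patient
    outcome: str  # good | poor | n/a
    session: int
    data: RoiTimeSeries
    motion: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.motion) != len(self.data.data):
            raise ValueError("motion table length must equal n_timepoints")


def ar1_series(
    phi: float,
    n: int,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    burn_in: int = 100,
    dt: float = 2.0,
) -> TimeSeries:
    """Stationary AR(1): y_t = φ·y_{t-1} + ε_t, ε ~ N(0, noise_sd²).

    Burn-in samples are generated and discarded so the returned stretch is
    (approximately) stationary; deterministic given the seed.
    """
    if not abs(phi) < 1:
        raise ValueError(f"|phi| must be < 1, got {phi}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, n + burn_in)
    y = signal.lfilter([1.0], [1.0, -phi], eps)
    return TimeSeries(values=y[burn_in:], dt=dt, label=f"ar1(phi={phi:g})")


def _ar1_matrix(
    phis: np.ndarray, n: int, noise_sd: float, rng: np.random.Generator,
    burn_in: int = 100,
) -> np.ndarray:
    """(n, len(phis)) matrix of independent AR(1) columns."""
    eps = rng.normal(0.0, noise_sd, (n + burn_in, phis.size))
    out = np.empty((n, phis.size))
    for j, phi in enumerate(phis):
        out[:, j] = signal.lfilter([1.0], [1.0, -phi], eps[:, j])[burn_in:]
    return out


def generate_motion(
    n_frames: int, rng: np.random.Generator, step_sd: float = 0.01
) -> pd.DataFrame:
    """Rigid-body motion table: independent Gaussian random walks (mm / deg)
    small enough that framewise displacement stays well under 1.5 mm/deg."""
    steps = rng.normal(0.0, step_sd, (n_frames, 6))
    steps[0] = 0.0
    return pd.DataFrame(np.cumsum(steps, axis=0), columns=list(MOTION_COLUMNS))


def framewise_displacement(motion: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-frame framewise displacement.

    FD_i = |Δd_ix| + |Δd_iy| + |Δd_iz| + |Δα_i| + |Δβ_i| + |Δγ_i| — the sum
    of absolute frame-to-frame changes of the six rigid-body parameters,
    rotations in their native angular units.  FD of the first frame is 0.
    """
    arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion must be an (n_frames, 6) table")
    if arr.shape[0] < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    fd = np.zeros(arr.shape[0])
    fd[1:] = np.abs(np.diff(arr, axis=0)).sum(axis=1)
    return fd


def _scan_rng(spec_seed: int, subject_code: int, session: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, subject_code, session]))


def _make_scan(
    spec: CohortSpec,
    parcellation: Parcellation,
    subject_id: str,
    subject_code: int,
    group: str,
    outcome: str,
    session: int,
) -> SubjectScan:
    rng = _scan_rng(spec.seed, subject_code, session)
    phis = np.array(
        [
            spec.phi_for(group, outcome, session, parcellation.network_of[r])
            for r in parcellation.roi_names
        ]
    )
    n = spec.n_timepoints
    data = _ar1_matrix(phis, n, spec.noise_sd, rng)
    if spec.network_noise_sd > 0:
        shared = {
            net: signal.lfilter(
                [1.0], [1.0, -spec.phi_for(group, outcome, session, net)],
                rng.normal(0.0, spec.network_noise_sd, n + 100),
            )[100:]
            for net in NETWORKS
        }
        for j, roi in enumerate(parcellation.roi_names):
            data[:, j] += shared[parcellation.network_of[roi]]
    frame = pd.DataFrame(data, columns=list(parcellation.roi_names))
    motion = generate_motion(n, rng)
    return SubjectScan(
        subject_id=subject_id,
        group=group,
        outcome=outcome,
        session=session,
        data=RoiTimeSeries(data=frame, tr=spec.tr, parcellation=parcellation),
        motion=motion,
    )


def generate_cohort(
    spec: CohortSpec | None = None, parcellation: Parcellation | None = None
) -> list[SubjectScan]:
    """All scans of the cohort (controls x 1 session, patients x 5 sessions).

    Fully reproducible from (spec, spec.seed); the first ``spec.n_good``
    patients carry the good-recovery label.
    """
    spec = spec if spec is not None else CohortSpec()
    spec.validate()
    parcellation = parcellation if parcellation is not None else default_parcellation()
    scans: list[SubjectScan] = []
    for i in range(spec.n_controls):
        scans.append(
            _make_scan(spec, parcellation, f"CTR{i + 1:02d}", i, "control", "n/a", 1)
        )
    for i in range(spec.n_patients):
        outcome = "good" if i < spec.n_good else "poor"
        for session in range(1, spec.n_sessions_patients + 1):
            scans.append(
                _make_scan(
                    spec,
                    parcellation,
                    f"PAT{i + 1:02d}",
                    1000 + i,
                    "patient",
                    outcome,
                    session,
                )
            )
    return scans


def save_cohort(scans: list[SubjectScan], out_dir: str | Path) -> Path:
    """Write one CSV per scan, one motion TSV per scan, and a JSON manifest."""
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(parents=True, exist_ok=True)
    manifest = {"tr": scans[0].data.tr, "scans": []}
    parc = scans[0].data.parcellation
    manifest["parcellation"] = {r: parc.network_of[r] for r in parc.roi_names}
    for scan in scans:
        stem = f"{scan.subject_id}_ses-{scan.session}"
        data_path = f"scans/{stem}.csv"
        motion_path = f"motion/{stem}_motion.tsv"
        scan.data.data.to_csv(out / data_path, index=False)
        scan.motion.to_csv(out / motion_path, sep="\t", index=False)
        manifest["scans"].append(
            {
                "subject": scan.subject_id,
                "group": scan.group,
                "outcome": scan.outcome,
                "session": scan.session,
                "data": data_path,
                "motion": motion_path,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def load_cohort(cohort_dir: str | Path) -> list[SubjectScan]:
    """Inverse of :func:`save_cohort`."""
    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    roi_names = tuple(manifest["parcellation"].keys())
    parc = Parcellation(roi_names=roi_names, network_of=manifest["parcellation"])
    scans = []
    for entry in manifest["scans"]:
        frame = pd.read_csv(root / entry["data"])
        motion = pd.read_csv(root / entry["motion"], sep="\t")
        scans.append(
            SubjectScan(
                subject_id=entry["subject"],
                group=entry["group"],
                outcome=entry["outcome"],
                session=entry["session"],
                data=RoiTimeSeries(
                    data=frame, tr=manifest["tr"], parcellation=parc
                ),
                motion=motion,
            )
        )
    return scans
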