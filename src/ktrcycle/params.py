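"""Parameter containers for the commitment-circuit simulator and virtual microscope.

The simulator is a phenomenological model of G0->S cell-cycle entry in
mitogen-stimulated epithelial cells: CDK4/6 switches on at a heterogeneous,
cell-specific onset time, inactivates Rb once it exceeds a threshold, Rb
inactivation de-represses an E2F-driven production term, and CDK2 activity
integrates that drive.  Once CDK2 activity has exceeded a commitment
threshold, Rb inactivation is locked in by CDK2-Rb positive feedback and
cell-cycle progression no longer requires CDK4/6.

All activities are in reporter ratio units (cytoplasmic/nuclear mean of a
kinase translocation reporter); times are in hours.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CircuitParams",
    "PerturbationSpec",
    "ImagingParams",
    "ParameterError",
    "load_params",
    "save_params",
    "paper_calibration",
]


class ParameterError(ValueError):
    """Raised when a parameter container violates its invariants."""


@dataclass(frozen=True)
class CircuitParams:
    """Generative parameters of the CDK4/6 -> Rb -> E2F -> CDK2 circuit.

    Attributes
    ----------
    p_active
        Probability that a cell activates CDK4/6 within the horizon.
    onset_min, onset_scale
        CDK4/6 onset times are drawn uniformly from
        ``[onset_min, onset_min + onset_scale]`` (hours): ``onset_min`` is
        the earliest possible activation after mitogen stimulation and
        ``onset_scale`` the width of the activation window.
    a46_max, rise_tau
        Plateau CDK4/6 activity (reporter units) and the exponential rise
        time constant (h) after onset.
    theta_rb
        CDK4/6 activity above which Rb is inactivated (reporter units).
    e2f_rate, e2f_decay
        Production (per h, while Rb is inactive) and first-order decay
        (per h) of the E2F transcriptional driver.
    cdk2_rate, cdk2_decay
        CDK2 activity production per E2F unit per hour, and first-order
        relaxation rate (per h) of CDK2 activity toward its quiescent
        baseline.
    a2_baseline
        Quiescent CDK2 activity on the reporter scale.
    theta_commit
        CDK2 activity that locks the Rb-inactivating positive feedback;
        crossing it commits the cell to the cycle irrespective of CDK4/6.
    theta_apc
        CDK2 activity at which the APC/C(Cdh1) degron starts accumulating.
    degron_rate
        Linear accumulation rate of the degron reporter after APC/C
        inactivation (a.u. per h).
    crosstalk_rho
        Fraction of CDK2 activity read by the CDK4/6 reporter (the
        cross-talk removed downstream by linear correction).
    noise_sd
        Gaussian observation noise on each reporter sample (reporter units).
    dt
        Sampling interval (h); 0.2 h corresponds to 12-min time-lapse.
    horizon
        Simulated duration (h) after mitogen stimulation.
    """

    p_active: float = 0.7
    onset_min: float = 3.0
    onset_scale: float = 10.0
    a46_max: float = 1.0
    rise_tau: float = 0.2
    theta_rb: float = 0.98
    e2f_rate: float = 0.97
    e2f_decay: float = 0.35
    cdk2_rate: float = 0.15
    cdk2_decay: float = 0.25
    a2_baseline: float = 0.1
    theta_commit: float = 1.0
    theta_apc: float = 1.2
    degron_rate: float = 0.25
    crosstalk_rho: float = 0.35
    noise_sd: float = 0.05
    dt: float = 0.2
    horizon: float = 14.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_active <= 1.0:
            raise ParameterError(f"p_active must be in [0, 1], got {self.p_active}")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.horizon <= 0:
            raise ParameterError("horizon must be positive")
        if not 0.0 <= self.crosstalk_rho < 1.0:
            raise ParameterError("crosstalk_rho must be in [0, 1)")
        if self.theta_commit <= 0:
            raise ParameterError("theta_commit must be positive")
        for name in (
            "onset_min", "onset_scale", "a46_max", "rise_tau", "theta_rb",
            "e2f_rate", "e2f_decay", "cdk2_rate", "cdk2_decay", "a2_baseline",
            "theta_apc", "degron_rate", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.horizon / self.dt)) + 1

    def replace(self, **kwargs) -> "CircuitParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PerturbationSpec:
    """Treatment applied at ``t_treat`` hours after stimulation.

    Modes
    -----
    none
        Untreated control.
    rapid_inhibitor
        Selective CDK4/6 inhibitor (e.g. palbociclib): CDK4/6 production is
        switched off at ``t_treat`` and activity decays with
        ``fast_decay_tau``.
    ncs_pulse
        DNA-damage pulse; modeled identically to ``rapid_inhibitor`` on
        CDK4/6 (both inactivate CDK4/6 rapidly).
    mitogen_withdrawal
        Mitogen removal: CDK4/6 stays active for a per-cell
        ``Uniform(withdrawal_delay_range)`` lag after ``t_treat`` (activity
        hysteresis), then decays.
    """

    mode: str = "none"
    t_treat: float = 11.0
    fast_decay_tau: float = 0.25
    withdrawal_delay_range: tuple[float, float] = (4.0, 5.0)

    _MODES = ("none", "rapid_inhibitor", "ncs_pulse", "mitogen_withdrawal")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ParameterError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if self.t_treat < 0:
            raise ParameterError("t_treat must be non-negative")
        if self.fast_decay_tau <= 0:
            raise ParameterError("fast_decay_tau must be positive")
        lo, hi = self.withdrawal_delay_range
        if not (0 <= lo <= hi):
            raise ParameterError("withdrawal_delay_range must be ordered and non-negative")

    def replace(self, **kwargs) -> "PerturbationSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ImagingParams:
    """Virtual-microscope geometry and noise.

    ``pixel_size_um`` defaults to 0.65 um/px, typical of a 20x objective
    with 2x2 camera binning.  ``bias_coeffs`` are the coefficients
    (c0, cx, cy, cxx, cxy, cyy) of a multiplicative quadratic illumination
    surface over normalized coordinates in [-1, 1]; ``None`` means flat
    illumination.
    """

    pixel_size_um: float = 0.65
    nucleus_radius_um: float = 8.0
    cyto_radius_um: float = 16.0
    field_shape: tuple[int, int] = (512, 512)
    bias_coeffs: tuple[float, ...] | None = None
    background: float = 100.0
    nuclear_amp: float = 2000.0
    reporter_total: float = 4.0e6
    degron_amp: float = 500.0
    gain: float = 1.0
    read_noise: float = 2.0
    jitter_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        if not self.nucleus_radius_um < self.cyto_radius_um:
            raise ParameterError("nucleus_radius_um must be < cyto_radius_um")

    def replace(self, **kwargs) -> "ImagingParams":
        return dataclasses.replace(self, **kwargs)


def _to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def save_params(path: str | Path, circuit: CircuitParams,
                pert: PerturbationSpec | None = None,
                imaging: ImagingParams | None = None) -> None:
    """Write a YAML (or JSON) parameter file with circuit/perturbation/imaging sections."""
    payload = {"circuit": _to_dict(circuit)}
    if pert is not None:
        payload["perturbation"] = _to_dict(pert)
    if imaging is not None:
        payload["imaging"] = _to_dict(imaging)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_params(path: str | Path) -> tuple[CircuitParams, PerturbationSpec, ImagingParams]:
    """Read a parameter file; absent sections fall back to defaults."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    circuit = CircuitParams(**_tuplify(payload.get("circuit", {})))
    pert = PerturbationSpec(**_tuplify(payload.get("perturbation", {})))
    imaging = ImagingParams(**_tuplify(payload.get("imaging", {})))
    return circuit, pert, imaging


def paper_calibration() -> CircuitParams:
    """Circuit parameters transcribed from the packaged ``calib_paper`` file.

    These encode the reported study conditions: 12-min sampling over a 14-h
    horizon, earliest CDK4/6 onset 3 h post-stimulation, reporter cross-talk
    0.35, commitment threshold 1 reporter unit, and an onset spread chosen so
    that ~40% of CDK4/6-activating cells have not yet activated CDK2 at the
    14-h fixation point.
    """
    ref = resources.files("ktrcycle.data").joinpath("calib_paper.yaml")
    with resources.as_file(ref) as p:
        circuit, _, _ = load_params(p)
    return circuit
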