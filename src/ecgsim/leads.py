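"""Limb-lead and augmented-lead algebra and 12-lead assembly.

The three bipolar limb leads follow Einthoven's triangle
(``I = LA - RA``, ``II = LL - RA``, ``III = LL - LA``, hence
``II = I + III``); the augmented limb leads reference each limb electrode to
Goldberger's central terminal (the mean of the other two), which makes their
sum vanish identically.  Precordial channels are referenced to the Wilson
central terminal, fixed at zero here by the gauge ``RA + LA + LL = 0`` --
any other gauge differs only by a common-mode offset that the lead
differences cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .integrator import ECGTrace, Trajectory, peak_magnitude, resample_uniform
from .models import LEADS, HeterogeneousParams, compose_ecg_heterogeneous

__all__ = ["ElectrodePotentials", "LeadSet", "limb_leads", "augmented_leads",
           "solve_electrode_potentials", "twelve_lead_profile"]

#: The leads whose composition weights must be shipped with a heterogeneous
#: parameter set: I and II pin down the limb electrodes, V1-V6 are composed
#: directly against the (zero) Wilson terminal.
COMPOSED_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class ElectrodePotentials:
    """Ground-referenced RA, LA, LL potentials sharing one time base."""

    RA: np.ndarray
    LA: np.ndarray
    LL: np.ndarray
    fs: float = 1.0

    def __post_init__(self) -> None:
        for name in ("RA", "LA", "LL"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.RA.shape == self.LA.shape == self.LL.shape):
            raise ValueError("electrode series must have equal lengths")
        for name in ("RA", "LA", "LL"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")


def limb_leads(e: ElectrodePotentials) -> tuple[ECGTrace, ECGTrace, ECGTrace]:
    """Bipolar limb leads ``I = LA - RA``, ``II = LL - RA``, ``III = LL - LA``."""
    return (ECGTrace(e.LA - e.RA, e.fs, "I"),
            ECGTrace(e.LL - e.RA, e.fs, "II"),
            ECGTrace(e.LL - e.LA, e.fs, "III"))


def augmented_leads(e: ElectrodePotentials) -> tuple[ECGTrace, ECGTrace, ECGTrace]:
    """Goldberger augmented leads; their sum is identically zero."""
    return (ECGTrace(e.RA - 0.5 * (e.LA + e.LL), e.fs, "aVR"),
            ECGTrace(e.LA - 0.5 * (e.RA + e.LL), e.fs, "aVL"),
            ECGTrace(e.LL - 0.5 * (e.RA + e.LA), e.fs, "aVF"))


def solve_electrode_potentials(lead_i: ECGTrace,
                               lead_ii: ECGTrace) -> ElectrodePotentials:
    """Unique electrode potentials with ``RA + LA + LL = 0`` reproducing
    leads I and II (Wilson central terminal at zero)."""
    if lead_i.values.shape != lead_ii.values.shape:
        raise ValueError("leads I and II must have equal lengths")
    if lead_i.fs != lead_ii.fs:
        raise ValueError("leads I and II must share a sampling rate")
    ra = -(lead_i.values + lead_ii.values) / 3.0
    return ElectrodePotentials(RA=ra, LA=ra + lead_i.values,
                               LL=ra + lead_ii.values, fs=lead_i.fs)


@dataclass(frozen=True)
class LeadSet:
    """The twelve standard channels sharing one time base.

    Construction validates completeness, a common sampling rate and length,
    the Einthoven identity ``II = I + III`` and the Goldberger identity
    ``aVR + aVL + aVF = 0`` (both to floating-point tolerance).
    """

    channels: Mapping[str, ECGTrace]

    def __post_init__(self) -> None:
        missing = [name for name in LEADS if name not in self.channels]
        if missing:
            raise ValueError(f"missing leads: {missing}")
        ref = self.channels["I"]
        for name in LEADS:
            tr = self.channels[name]
            if tr.fs != ref.fs or tr.values.size != ref.values.size:
                raise ValueError(
                    f"lead {name} does not share the common time base")
        scale = max(peak_magnitude(self.channels[n].values) for n in LEADS)
        tol = 64.0 * np.finfo(float).eps * max(scale, 1e-30)
        ein = self.channels["II"].values - (self.channels["I"].values
                                            + self.channels["III"].values)
        gold = (self.channels["aVR"].values + self.channels["aVL"].values
                + self.channels["aVF"].values)
        if np.max(np.abs(ein)) > tol:
            raise ValueError("Einthoven identity II = I + III violated")
        if np.max(np.abs(gold)) > tol:
            raise ValueError("Goldberger identity aVR + aVL + aVF = 0 violated")

    def __getitem__(self, name: str) -> ECGTrace:
        return self.channels[name]

    @property
    def fs(self) -> float:
        return self.channels["I"].fs

    def traces(self) -> list[ECGTrace]:
        return [self.channels[name] for name in LEADS]


def twelve_lead_profile(trajectory: Trajectory,
                        params: HeterogeneousParams,
                        *,
                        fs: float = 500.0,
                        gain: float = 1.0,
                        time_scale: float = 1.0,
                        transient: float | None = None) -> LeadSet:
    """Assemble a 12-lead profile from a heterogeneous-model trajectory.

    Leads I, II and the precordials V1-V6 are composed directly from the
    muscle variables through their per-lead weight rows; the electrode
    potentials are then solved from I and II under the zero-sum gauge, and
    III, aVR, aVL, aVF follow from the lead algebra.  One common amplitude
    scale -- calibrated so lead II's R peak equals ``gain`` mV -- is applied
    to every channel, so the lead identities survive calibration exactly.
    """
    if trajectory.model != "heterogeneous":
        raise ValueError("a heterogeneous-model trajectory is required")
    missing = [ch for ch in COMPOSED_LEADS if ch not in params.alphas]
    if missing:
        raise ValueError(
            f"missing per-lead weight rows for channels: {missing}")

    composed = {ch: np.asarray(
        compose_ecg_heterogeneous(trajectory.states, params, ch), dtype=float)
        for ch in COMPOSED_LEADS}
    ra = -(composed["I"] + composed["II"]) / 3.0
    la = ra + composed["I"]
    ll = ra + composed["II"]
    signals = dict(composed)
    signals["III"] = ll - la
    signals["aVR"] = ra - 0.5 * (la + ll)
    signals["aVL"] = la - 0.5 * (ra + ll)
    signals["aVF"] = ll - 0.5 * (ra + la)

    t_out = trajectory.t / time_scale
    total = t_out[-1] - t_out[0]
    if transient is None:
        transient = min(0.2 * total, 5.0)
    i0 = int(np.searchsorted(t_out, t_out[0] + transient))

    resampled = {}
    for name in LEADS:
        vals, _ = resample_uniform(t_out[i0:], signals[name][i0:], fs)
        resampled[name] = vals
    mag = peak_magnitude(resampled["II"])
    if mag > 0:
        scale = gain / mag
    else:
        warnings.warn("lead II is flat; gain calibration falls back to "
                      "unit scale", stacklevel=2)
        scale = 1.0
    channels = {name: ECGTrace(resampled[name] * scale, fs, name)
                for name in LEADS}
    return LeadSet(channels=channels)
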