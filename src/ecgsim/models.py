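"""Dynamical models of macroscopic heartbeat dynamics.

Four model families are implemented, each producing a synthetic ECG as a
linear read-out of a low-dimensional state trajectory:

``heterogeneous``
    A cascade of three modified Van der Pol oscillators standing for the
    natural pacemakers (sinoatrial node, atrioventricular node, His-Purkinje
    system) coupled through time-delayed velocity terms, driving four
    modified FitzHugh-Nagumo oscillators for the muscle responses (P wave,
    atrial repolarization Ta, QRS complex, T wave).  The ECG is a weighted
    combination of the four muscle depolarization variables, with per-lead
    weight rows enabling a full 12-lead profile.

``reaction_diffusion``
    A four-variable network obtained from the spatial discretization of the
    BVAM reaction-diffusion system; the ECG is a linear mixing of the four
    state variables.

``ring``
    A ring of three delay-coupled modified Van der Pol oscillators (SA, AV,
    HP), each optionally driven by a sinusoidal forcing term; the ECG is an
    affine combination of the three position variables.

``quasi_periodic``
    A planar limit cycle whose phase angle sweeps seven Gaussian "push-pull"
    events (P-, P+, Q, R, S, T-, T+) acting on three waveform channels
    (P wave, QRS complex, T wave); the ECG is the sum of the channels.

All derivative functions are pure and side-effect free; time-delayed inputs
are supplied by the caller (see :mod:`ecgsim.integrate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

PACEMAKERS = ("SA", "AV", "HP")
MUSCLES = ("P", "Ta", "QRS", "T")
KERNELS = ("P-", "P+", "Q", "R", "S", "T-", "T+")
#: Directed coupling edges of the ring model, named target-source: the entry
#: "AV-SA" is the coupling constant appearing in the AV equation, acting on
#: the (possibly delayed) SA position.
RING_COUPLINGS = ("SA-AV", "SA-HP", "AV-SA", "AV-HP", "HP-SA", "HP-AV")
#: State-vector index of the source-node position for each ring coupling.
RING_COUPLING_SOURCE = (2, 4, 0, 4, 0, 2)
#: Kernels feeding each waveform channel of the quasi-periodic model.
CHANNEL_KERNELS = {"P": ("P-", "P+"), "C": ("Q", "R", "S"), "T": ("T-", "T+")}
LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
         "V1", "V2", "V3", "V4", "V5", "V6")

STATE_DIM = {
    "heterogeneous": 14,
    "reaction_diffusion": 4,
    "ring": 6,
    "quasi_periodic": 5,
}
MODELS = tuple(STATE_DIM)


def _check_finite(obj: str, **fields: float) -> None:
    for name, value in fields.items():
        if not math.isfinite(value):
            raise ValueError(f"{obj}.{name} must be finite, got {value!r}")


def wrap_angle(delta):
    """Wrap an angle difference to the interval [-pi, pi).

    Vectorized; the branch cut sits at the antipode so the wrapped difference
    is continuous everywhere except across +-pi.
    """
    return (np.asarray(delta) + np.pi) % (2.0 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# Heterogeneous oscillator network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PacemakerParams:
    """Modified Van der Pol pacemaker.

    The velocity equation is
    ``dy/dt = -a (x^2 - u) y - f x (x + d)(x + e) + K (y_up(t - tau) - y)``
    where ``y_up`` is the velocity of the upstream pacemaker.  The sinoatrial
    node is autonomous (``K = 0``).
    """

    a: float
    u: float
    f: float
    d: float
    e: float
    K: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        _check_finite("PacemakerParams", a=self.a, u=self.u, f=self.f,
                      d=self.d, e=self.e, K=self.K, tau=self.tau)
        if self.tau < 0:
            raise ValueError(f"coupling delay tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class MuscleParams:
    """Modified FitzHugh-Nagumo muscle-response oscillator.

    ``dz/dt = k (-c z (z - w1)(z - w2) - b v - g v z + I)`` and
    ``dv/dt = k h (z - v)``, with the stimulation current
    ``I = C Y H(Y)`` gated by the unit step (``H(0) = 0``).
    """

    k: float
    c: float
    w1: float
    w2: float
    b: float
    g: float
    h: float
    C: float

    def __post_init__(self) -> None:
        _check_finite("MuscleParams", k=self.k, c=self.c, w1=self.w1,
                      w2=self.w2, b=self.b, g=self.g, h=self.h, C=self.C)


@dataclass(frozen=True)
class HeterogeneousParams:
    """Full parameter set of the heterogeneous oscillator network.

    ``alphas`` maps a lead name to its four composition weights
    ``(alpha1, alpha2, alpha3, alpha4)`` applied to the muscle variables
    ``z1..z4`` (P, Ta, QRS, T); ``z0`` is the baseline offset, optionally
    overridden per lead through ``z0_leads``.
    """

    pacemakers: tuple[PacemakerParams, PacemakerParams, PacemakerParams]
    muscles: tuple[MuscleParams, MuscleParams, MuscleParams, MuscleParams]
    z0: float = 0.0
    alphas: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {"II": (1.0, 1.0, 1.0, 1.0)})
    z0_leads: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pacemakers) != 3:
            raise ValueError("exactly 3 pacemakers (SA, AV, HP) required")
        if len(self.muscles) != 4:
            raise ValueError("exactly 4 muscles (P, Ta, QRS, T) required")
        _check_finite("HeterogeneousParams", z0=self.z0)
        for lead, w in self.alphas.items():
            if len(w) != 4:
                raise ValueError(
                    f"lead {lead!r} needs exactly 4 weights, got {len(w)}")

    def baseline(self, channel: str) -> float:
        return float(self.z0_leads.get(channel, self.z0))


def heterogeneous_deriv(state, params: HeterogeneousParams,
                        delayed: Sequence[float]):
    """Time derivative of the 14-dimensional heterogeneous-network state.

    State layout: ``[x_SA, y_SA, x_AV, y_AV, x_HP, y_HP,
    z_P, v_P, z_Ta, v_Ta, z_QRS, v_QRS, z_T, v_T]``.

    ``delayed`` holds the delayed upstream velocity seen by each pacemaker:
    ``delayed[1] = y_SA(t - tau_AV)`` and ``delayed[2] = y_AV(t - tau_HP)``;
    ``delayed[0]`` is ignored (the SA node is autonomous).
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (14,):
        raise ValueError(f"heterogeneous state must have dimension 14, "
                         f"got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite state rejected")
    d = np.asarray(delayed, dtype=float)
    if d.shape != (3,):
        raise ValueError("need one delayed velocity value per pacemaker")

    out = np.empty(14)
    for i, p in enumerate(params.pacemakers):
        x, y = s[2 * i], s[2 * i + 1]
        dy = -p.a * (x * x - p.u) * y - p.f * x * (x + p.d) * (x + p.e)
        if p.K != 0.0:
            if not math.isfinite(d[i]):
                raise ValueError(
                    f"pacemaker {PACEMAKERS[i]} is coupled (K != 0) but its "
                    f"delayed value is not finite")
            dy += p.K * (d[i] - y)
        out[2 * i] = y
        out[2 * i + 1] = dy

    y1, y3 = s[1], s[5]
    drives = (y1, -y1, y3, -y3)
    for j, m in enumerate(params.muscles):
        z, v = s[6 + 2 * j], s[7 + 2 * j]
        Yj = drives[j]
        current = m.C * Yj if Yj > 0.0 else 0.0
        out[6 + 2 * j] = m.k * (-m.c * z * (z - m.w1) * (z - m.w2)
                                - m.b * v - m.g * v * z + current)
        out[7 + 2 * j] = m.k * m.h * (z - v)
    return out


def stimulation_current(params: MuscleParams, Y: float) -> float:
    """Stimulation current ``I = C * Y * H(Y)`` with ``H(0) = 0``."""
    return params.C * Y if Y > 0.0 else 0.0


def compose_ecg_heterogeneous(state, params: HeterogeneousParams,
                              channel: str = "II"):
    """ECG potential ``z0 + a1 z1 - a2 z2 + a3 z3 + a4 z4`` for one lead.

    ``state`` may be a single state vector or an array of shape ``(..., 14)``
    (a whole trajectory); the composition is applied along the last axis.
    """
    try:
        a1, a2, a3, a4 = params.alphas[channel]
    except KeyError:
        available = ", ".join(sorted(params.alphas))
        raise KeyError(
            f"no composition weights for channel {channel!r}; "
            f"available channels: {available}") from None
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != 14:
        raise ValueError("heterogeneous state must have dimension 14")
    z1, z2, z3, z4 = s[..., 6], s[..., 8], s[..., 10], s[..., 12]
    return params.baseline(channel) + a1 * z1 - a2 * z2 + a3 * z3 + a4 * z4


# ---------------------------------------------------------------------------
# Discretized reaction-diffusion (BVAM) network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionDiffusionParams:
    """Parameters of the four-variable discretized BVAM network.

    ``H`` and ``C`` select the dynamical regime, ``beta`` is the local
    interaction strength, ``K1..K4`` are the ECG mixing weights and
    ``Gamma_t`` the time-compression factor (output seconds =
    model time / ``Gamma_t``).
    """

    H: float
    C: float
    beta: float
    K1: float
    K2: float
    K3: float
    K4: float
    Gamma_t: float = 1.0

    def __post_init__(self) -> None:
        _check_finite("ReactionDiffusionParams", H=self.H, C=self.C,
                      beta=self.beta, K1=self.K1, K2=self.K2, K3=self.K3,
                      K4=self.K4, Gamma_t=self.Gamma_t)


def rd_deriv(state, params: ReactionDiffusionParams):
    """Time derivative of the discretized reaction-diffusion state.

    The two oscillator pairs are asymmetrically coupled: ``beta (x4 - x2)``
    enters the second equation and ``2 beta (x2 - x4)`` the fourth.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (4,):
        raise ValueError(f"reaction-diffusion state must have dimension 4, "
                         f"got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite state rejected")
    x1, x2, x3, x4 = s
    H, C, b = params.H, params.C, params.beta
    return np.array([
        x1 - x2 - C * x1 * x2 - x1 * x2 * x2,
        H * x1 - 3.0 * x2 + C * x1 * x2 + x1 * x2 * x2 + b * (x4 - x2),
        x3 - x4 - C * x3 * x4 - x3 * x4 * x4,
        H * x3 - 3.0 * x4 + C * x3 * x4 + x3 * x4 * x4 + 2.0 * b * (x2 - x4),
    ])


def compose_ecg_rd(state, params: ReactionDiffusionParams):
    """ECG potential ``K1 x1 + K2 x2 + K3 x3 + K4 x4`` (last-axis compose)."""
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != 4:
        raise ValueError("reaction-diffusion state must have dimension 4")
    return (params.K1 * s[..., 0] + params.K2 * s[..., 1]
            + params.K3 * s[..., 2] + params.K4 * s[..., 3])


# ---------------------------------------------------------------------------
# Ring of three delay-coupled oscillators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingNodeParams:
    """One modified Van der Pol node of the ring (SA, AV or HP).

    ``rho`` and ``omega`` are the amplitude and angular frequency of the
    additive sinusoidal drive ``rho sin(omega t)``.
    """

    a: float
    w1: float
    w2: float
    d: float
    e: float
    rho: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        _check_finite("RingNodeParams", a=self.a, w1=self.w1, w2=self.w2,
                      d=self.d, e=self.e, rho=self.rho, omega=self.omega)


@dataclass(frozen=True)
class RingCoupling:
    """Directed coupling ``k (x_target - x_source(t - tau))``."""

    k: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        _check_finite("RingCoupling", k=self.k, tau=self.tau)
        if self.tau < 0:
            raise ValueError(f"transport delay must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class RingParams:
    """Parameters of the three-oscillator ring model."""

    nodes: Mapping[str, RingNodeParams]
    couplings: Mapping[str, RingCoupling]
    alpha0: float
    alpha1: float
    alpha3: float
    alpha5: float
    beta_G: float
    beta_T: float = 1.0

    def __post_init__(self) -> None:
        missing = [n for n in PACEMAKERS if n not in self.nodes]
        if missing:
            raise ValueError(f"missing ring nodes: {missing}")
        missing = [c for c in RING_COUPLINGS if c not in self.couplings]
        if missing:
            raise ValueError(f"missing ring couplings: {missing}")
        _check_finite("RingParams", alpha0=self.alpha0, alpha1=self.alpha1,
                      alpha3=self.alpha3, alpha5=self.alpha5,
                      beta_G=self.beta_G, beta_T=self.beta_T)
        if self.beta_G == 0.0:
            raise ValueError("beta_G must be nonzero")


def ring_deriv(state, t: float, params: RingParams, delayed):
    """Time derivative of the six-dimensional ring state.

    State layout: ``[x1, x2, x3, x4, x5, x6]`` with positions ``x1, x3, x5``
    and velocities ``x2, x4, x6`` for SA, AV, HP.  ``delayed`` supplies the
    delayed source position for each edge of :data:`RING_COUPLINGS`, either
    as a mapping or as a sequence in that order; an entry may be omitted (or
    non-finite) only if the edge's coupling constant is zero.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (6,):
        raise ValueError(f"ring state must have dimension 6, got {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite state rejected")
    if isinstance(delayed, Mapping):
        dvals = [delayed.get(name, math.nan) for name in RING_COUPLINGS]
    else:
        dvals = list(delayed)
        if len(dvals) != 6:
            raise ValueError("need 6 delayed values, one per ring coupling")

    out = np.empty(6)
    for i, name in enumerate(PACEMAKERS):
        node = params.nodes[name]
        pos, vel = s[2 * i], s[2 * i + 1]
        acc = (-node.a * vel * (pos - node.w1) * (pos - node.w2)
               + node.rho * math.sin(node.omega * t)
               - pos * (pos - node.d) * (pos - node.e))
        for c in (2 * i, 2 * i + 1):
            k = params.couplings[RING_COUPLINGS[c]].k
            if k != 0.0:
                if not math.isfinite(dvals[c]):
                    raise ValueError(
                        f"coupling {RING_COUPLINGS[c]} has k={k} but no "
                        f"delayed source value was supplied")
                acc -= k * (pos - dvals[c])
        out[2 * i] = vel
        out[2 * i + 1] = acc
    return out


def compose_ecg_ring(state, params: RingParams):
    """ECG potential ``(alpha0 + alpha1 x1 + alpha3 x3 + alpha5 x5) beta_G``."""
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != 6:
        raise ValueError("ring state must have dimension 6")
    return (params.alpha0 + params.alpha1 * s[..., 0]
            + params.alpha3 * s[..., 2] + params.alpha5 * s[..., 4]) * params.beta_G


# ---------------------------------------------------------------------------
# Quasi-periodic Gaussian-kernel model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianKernel:
    """One push-pull event: amplitude ``a``, angular width ``b`` (rad),
    angular position ``theta`` (rad) on the unit limit cycle."""

    a: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        _check_finite("GaussianKernel", a=self.a, b=self.b, theta=self.theta)
        if self.b <= 0:
            raise ValueError(f"kernel width must be positive, got {self.b}")
        if not -math.pi <= self.theta <= math.pi:
            raise ValueError(
                f"kernel angle must lie in [-pi, pi], got {self.theta}")


@dataclass(frozen=True)
class QuasiPeriodicParams:
    """Parameters of the quasi-periodic Gaussian-kernel model.

    Exactly one of ``omega`` (constant angular frequency, rad per model
    second) or ``tachogram`` (a beat-to-beat interval specification, see
    :mod:`ecgsim.tachogram`) must be given.  ``A`` and ``fr`` set the
    respiratory baseline wander amplitude (model units) and frequency (Hz).
    """

    kernels: Mapping[str, GaussianKernel]
    omega: float | None = None
    tachogram: object | None = None
    A: float = 0.005
    fr: float = 0.25

    def __post_init__(self) -> None:
        missing = [k for k in KERNELS if k not in self.kernels]
        if missing:
            raise ValueError(f"missing Gaussian kernels: {missing}")
        extra = [k for k in self.kernels if k not in KERNELS]
        if extra:
            raise ValueError(f"unknown Gaussian kernels: {extra}")
        if (self.omega is None) == (self.tachogram is None):
            raise ValueError("exactly one of omega and tachogram must be set")
        if self.omega is not None:
            _check_finite("QuasiPeriodicParams", omega=self.omega)
        _check_finite("QuasiPeriodicParams", A=self.A, fr=self.fr)
        if self.fr < 0:
            raise ValueError(f"respiratory frequency must be >= 0, got {self.fr}")

    @classmethod
    def from_heart_rate(cls, kernels, heart_rate: float,
                        **kwargs) -> "QuasiPeriodicParams":
        """Build a constant-rate parameter set from a heart rate in bpm."""
        return cls(kernels=kernels, omega=2.0 * math.pi * heart_rate / 60.0,
                   **kwargs)

    @property
    def heart_rate(self) -> float | None:
        """Mean heart rate in beats per minute (None in tachogram mode)."""
        if self.omega is None:
            return None
        return 60.0 * self.omega / (2.0 * math.pi)


def with_width_scaled_amplitudes(params: QuasiPeriodicParams) -> QuasiPeriodicParams:
    """Return a copy with every kernel amplitude replaced by ``a * b**2``.

    Some parameterizations of this model family quote ``alpha_i`` such that
    the effective push-pull amplitude is ``alpha_i b_i**2``; this transform
    converts such a table.  The shipped presets use amplitudes directly, so
    this is opt-in.
    """
    kernels = {name: replace(k, a=k.a * k.b * k.b)
               for name, k in params.kernels.items()}
    return replace(params, kernels=kernels)


def baseline_wander(t, params: QuasiPeriodicParams):
    """Respiratory baseline ``A sin(2 pi fr t)`` (shared by P, C, T)."""
    return params.A * np.sin(2.0 * np.pi * params.fr * np.asarray(t, float))


def kernel_pushpull(kernel: GaussianKernel, theta):
    """Push-pull term ``a dtheta exp(-dtheta^2 / (2 b^2))`` of one kernel.

    ``dtheta = wrap(theta - theta_i)``; the term is an odd function of the
    wrapped angle difference.
    """
    dth = wrap_angle(np.asarray(theta, float) - kernel.theta)
    return kernel.a * dth * np.exp(-dth * dth / (2.0 * kernel.b * kernel.b))


def qp_deriv(state, t: float, params: QuasiPeriodicParams,
             omega: float | None = None):
    """Time derivative of the quasi-periodic state ``[x, y, P, C, T]``.

    The planar subsystem has an attracting unit limit cycle
    (``dx/dt = alpha x - omega y``, ``dy/dt = alpha y + omega x`` with
    ``alpha = 1 - sqrt(x^2 + y^2)``); each waveform channel relaxes toward
    the respiratory baseline while the Gaussian kernels push and pull it as
    the phase angle passes their positions.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (5,):
        raise ValueError(f"quasi-periodic state must have dimension 5, "
                         f"got {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite state rejected")
    if omega is None:
        omega = params.omega
    if omega is None:
        raise ValueError("tachogram mode requires an explicit omega(t) value")

    x, y = s[0], s[1]
    alpha = 1.0 - math.hypot(x, y)
    theta = math.atan2(y, x)
    z0 = float(baseline_wander(t, params))

    out = np.empty(5)
    out[0] = alpha * x - omega * y
    out[1] = alpha * y + omega * x
    for ci, channel in enumerate(("P", "C", "T")):
        push = 0.0
        for name in CHANNEL_KERNELS[channel]:
            push += float(kernel_pushpull(params.kernels[name], theta))
        out[2 + ci] = -push - (s[2 + ci] - z0)
    return out


def compose_ecg_qp(state):
    """ECG potential ``P + C + T`` (last-axis compose)."""
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != 5:
        raise ValueError("quasi-periodic state must have dimension 5")
    return s[..., 2] + s[..., 3] + s[..., 4]
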