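"""Beat-to-beat (RR) interval series with a bimodal power spectrum.

Heart-rate variability in sinus rhythm concentrates in two bands: a
low-frequency (Mayer-wave, sympathovagal) band near 0.1 Hz and a
high-frequency (respiratory sinus arrhythmia) band near 0.25 Hz.  The
generator below realizes a stationary Gaussian interval series whose power
spectrum is the sum of two Gaussian lobes at those center frequencies, then
rescales it to a requested mean and standard deviation of heart rate.  It is
used by the quasi-periodic model to drive an irregular (e.g., atrial
fibrillation-like) rotation frequency around the limit cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TachogramSpec:
    """Specification of an RR-interval series.

    Parameters
    ----------
    mean_hr, std_hr : float
        Mean and standard deviation of heart rate, beats per minute.
    f_lf, f_hf : float
        Center frequencies (Hz) of the low- and high-frequency lobes.
    c_lf, c_hf : float
        Standard deviations (Hz) of the two spectral lobes.
    lf_hf_ratio : float
        Power ratio between the low- and high-frequency lobes.
    """

    mean_hr: float
    std_hr: float
    f_lf: float = 0.1
    f_hf: float = 0.25
    c_lf: float = 0.01
    c_hf: float = 0.01
    lf_hf_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (self.mean_hr > 0 and np.isfinite(self.mean_hr)):
            raise ValueError(f"mean_hr must be positive, got {self.mean_hr}")
        if not (self.std_hr >= 0 and np.isfinite(self.std_hr)):
            raise ValueError(f"std_hr must be >= 0, got {self.std_hr}")
        for name in ("f_lf", "f_hf", "c_lf", "c_hf", "lf_hf_ratio"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be positive, got {v}")


def rr_series(spec: TachogramSpec, n_beats: int,
              rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw ``n_beats`` successive RR intervals (seconds).

    The series is built in the frequency domain: amplitudes follow the
    square root of the bimodal spectrum, phases are uniform, and the inverse
    transform is standardized to the requested mean/std.  Intervals are
    clipped to [0.3, 2.0] times the mean interval so a rare large excursion
    cannot produce a non-physical beat.  Deterministic for a fixed ``rng``
    seed.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(rng)

    mean_rr = 60.0 / spec.mean_hr
    # std of RR from std of HR by local linearization of rr = 60/hr
    std_rr = spec.std_hr * 60.0 / spec.mean_hr ** 2

    n = max(int(n_beats), 16)
    # beat index plays the role of time, sampled at the mean beat spacing
    freqs = np.fft.rfftfreq(2 * n, d=mean_rr)
    power = (spec.lf_hf_ratio
             * np.exp(-0.5 * ((freqs - spec.f_lf) / spec.c_lf) ** 2)
             + np.exp(-0.5 * ((freqs - spec.f_hf) / spec.c_hf) ** 2))
    power[0] = 0.0
    amplitude = np.sqrt(power)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amplitude.size)
    spectrum = amplitude * np.exp(1j * phases)
    series = np.fft.irfft(spectrum, n=2 * n)[:n_beats]

    sd = series.std()
    if sd > 0 and std_rr > 0:
        series = (series - series.mean()) / sd * std_rr
    else:
        series = np.zeros(n_beats)
    rr = mean_rr + series
    return np.clip(rr, 0.3 * mean_rr, 2.0 * mean_rr)


def omega_per_step(spec: TachogramSpec, n_steps: int, step: float,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Piecewise-constant angular frequency on the integration grid.

    Beat ``k`` occupies the model-time span ``[T_k, T_k + RR_k)`` with
    angular frequency ``2 pi / RR_k``, so each beat completes exactly one
    revolution of the limit cycle.
    """
    duration = n_steps * step
    est = int(np.ceil(duration / (0.3 * 60.0 / spec.mean_hr))) + 2
    rr = rr_series(spec, est, rng)
    omega = np.empty(n_steps)
    beat = 0
    t_next = rr[0]
    w = 2.0 * np.pi / rr[0]
    for i in range(n_steps):
        t = i * step
        while t >= t_next and beat < rr.size - 1:
            beat += 1
            t_next += rr[beat]
            w = 2.0 * np.pi / rr[beat]
        omega[i] = w
    return omega
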