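"""Registry, validation and serialization of rhythm presets.

A preset is the software twin of one row of the device's parameter tables:
a model identifier, a rhythm name, a complete named-parameter set, a
time-scale factor and a target R-peak gain.  Arrhythmia presets are stored
as a sparse override of the model's normal-rhythm row, mirroring the fact
that only the listed parameters change between the normal state and each
disorder; the overridden field paths are retained on the preset so the
difference is inspectable.

Preset files are JSON; angular quantities may be written as exact
pi-fraction strings such as ``"-3*pi/8"``.
"""

from __future__ import annotations

import copy
import json
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Any, Mapping

from . import models
from .tachogram import TachogramSpec

__all__ = ["RhythmPreset", "ValidationIssue", "ValidationReport",
           "get_preset", "list_presets", "validate_preset", "preset_raw",
           "build_params", "parse_angle", "PresetError", "GAIN_RANGE"]

#: Permitted R-peak gain window in millivolts (the output amplitude range
#: a bedside electrocardiograph is expected to accept).
GAIN_RANGE = (0.5, 4.0)

_PACEMAKER_FIELDS = ("a", "u", "f", "d", "e", "K", "tau")
_MUSCLE_FIELDS = ("k", "c", "w1", "w2", "b", "g", "h", "C")
_RD_FIELDS = ("H", "C", "beta", "K1", "K2", "K3", "K4")
_RING_NODE_FIELDS = ("a", "w1", "w2", "d", "e", "rho", "omega")

_PI_PATTERN = re.compile(
    r"^\s*([+-]?)\s*(\d+(?:\.\d+)?)?\s*\*?\s*pi\s*(?:/\s*(\d+(?:\.\d+)?))?\s*$",
    re.IGNORECASE)


class PresetError(KeyError):
    """Unknown preset key; the message lists the valid alternatives."""


def parse_angle(value) -> float:
    """Parse a number or an exact pi-fraction string like ``"-3*pi/8"``."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    m = _PI_PATTERN.match(text)
    if m:
        sign = -1.0 if m.group(1) == "-" else 1.0
        coef = float(m.group(2)) if m.group(2) else 1.0
        den = float(m.group(3)) if m.group(3) else 1.0
        return sign * coef * math.pi / den
    return float(text)


@dataclass(frozen=True)
class ValidationIssue:
    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.path}: {self.message}"


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "valid"
        return "invalid preset:\n" + "\n".join(f"  - {i}" for i in self.issues)


@dataclass(frozen=True)
class RhythmPreset:
    """One (model, rhythm) entry of the registry.

    ``params`` is the fully built, validated parameter object of the owning
    model; ``overrides`` lists the dotted parameter paths in which this
    preset differs from the ``base`` rhythm it was derived from.
    """

    model: str
    rhythm: str
    params: Any
    time_scale: float
    gain: float
    notes: str = ""
    base: str | None = None
    overrides: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Raw-dict validation
# ---------------------------------------------------------------------------

def _num(issues, raw, path, key, *, minimum=None, strict_min=False):
    if key not in raw:
        issues.append(ValidationIssue(f"{path}.{key}" if path else key,
                                      "missing required field"))
        return None
    try:
        v = float(raw[key])
    except (TypeError, ValueError):
        issues.append(ValidationIssue(f"{path}.{key}", "not a number"))
        return None
    if not math.isfinite(v):
        issues.append(ValidationIssue(f"{path}.{key}", "must be finite"))
        return None
    if minimum is not None:
        if strict_min and v <= minimum:
            issues.append(ValidationIssue(
                f"{path}.{key}", f"must be > {minimum}, got {v}"))
        elif not strict_min and v < minimum:
            issues.append(ValidationIssue(
                f"{path}.{key}", f"must be >= {minimum}, got {v}"))
    return v


def _validate_heterogeneous(raw, issues) -> None:
    pacemakers = raw.get("pacemakers", {})
    for name in models.PACEMAKERS:
        if name not in pacemakers:
            issues.append(ValidationIssue(f"pacemakers.{name}",
                                          "missing pacemaker"))
            continue
        for f in _PACEMAKER_FIELDS:
            _num(issues, pacemakers[name], f"pacemakers.{name}", f,
                 minimum=0.0 if f == "tau" else None)
    muscles = raw.get("muscles", {})
    for name in models.MUSCLES:
        if name not in muscles:
            issues.append(ValidationIssue(f"muscles.{name}", "missing muscle"))
            continue
        for f in _MUSCLE_FIELDS:
            _num(issues, muscles[name], f"muscles.{name}", f)
    _num(issues, raw, "", "z0")
    alphas = raw.get("alphas", {})
    if not alphas:
        issues.append(ValidationIssue("alphas",
                                      "at least one lead weight row required"))
    for lead, weights in alphas.items():
        if len(weights) != 4:
            issues.append(ValidationIssue(
                f"alphas.{lead}", f"needs exactly 4 weights, got {len(weights)}"))


def _validate_rd(raw, issues) -> None:
    for f in _RD_FIELDS:
        _num(issues, raw, "", f)


def _validate_ring(raw, issues) -> None:
    nodes = raw.get("nodes", {})
    for name in models.PACEMAKERS:
        if name not in nodes:
            issues.append(ValidationIssue(f"nodes.{name}", "missing node"))
            continue
        for f in _RING_NODE_FIELDS:
            _num(issues, nodes[name], f"nodes.{name}", f)
    couplings = raw.get("couplings", {})
    for name in models.RING_COUPLINGS:
        if name not in couplings:
            issues.append(ValidationIssue(f"couplings.{name}",
                                          "missing coupling"))
            continue
        _num(issues, couplings[name], f"couplings.{name}", "k")
        _num(issues, couplings[name], f"couplings.{name}", "tau", minimum=0.0)
    for f in ("alpha0", "alpha1", "alpha3", "alpha5"):
        _num(issues, raw, "", f)
    bg = _num(issues, raw, "", "beta_G")
    if bg == 0.0:
        issues.append(ValidationIssue("beta_G", "must be nonzero"))


def _validate_qp(raw, issues) -> None:
    kernels = raw.get("kernels", {})
    for name in models.KERNELS:
        if name not in kernels:
            issues.append(ValidationIssue(f"kernels.{name}", "missing kernel"))
            continue
        entry = kernels[name]
        if len(entry) != 3:
            issues.append(ValidationIssue(
                f"kernels.{name}", "expected [amplitude, width, angle]"))
            continue
        a, b, theta = entry
        try:
            b = float(b)
        except (TypeError, ValueError):
            issues.append(ValidationIssue(f"kernels.{name}",
                                          "width not a number"))
            continue
        if not b > 0:
            issues.append(ValidationIssue(f"kernels.{name}",
                                          "width must be positive"))
        try:
            parse_angle(theta)
        except ValueError:
            issues.append(ValidationIssue(f"kernels.{name}",
                                          f"cannot parse angle {theta!r}"))
    hr = raw.get("heart_rate")
    tacho = raw.get("tachogram")
    if hr is None and tacho is None:
        issues.append(ValidationIssue(
            "heart_rate", "either heart_rate or tachogram is required"))
    if hr is not None and not (isinstance(hr, (int, float)) and hr > 0):
        issues.append(ValidationIssue("heart_rate", "must be positive"))
    if tacho is not None:
        try:
            TachogramSpec(**tacho)
        except (TypeError, ValueError) as err:
            issues.append(ValidationIssue("tachogram", str(err)))
    if "fr" in raw:
        _num(issues, raw, "", "fr", minimum=0.0)
    if "A" in raw:
        _num(issues, raw, "", "A")


_VALIDATORS = {
    "heterogeneous": _validate_heterogeneous,
    "reaction_diffusion": _validate_rd,
    "ring": _validate_ring,
    "quasi_periodic": _validate_qp,
}


# ---------------------------------------------------------------------------
# Typed-parameter builders (assume a validated raw dict)
# ---------------------------------------------------------------------------

def build_params(model: str, raw: Mapping, time_scale: float = 1.0):
    """Build the typed parameter object of ``model`` from a raw mapping.

    The time-scale factor of the reaction-diffusion and ring models lives on
    the preset; it is mirrored into ``Gamma_t`` / ``beta_T`` here so the
    parameter object is self-describing.
    """
    if model == "heterogeneous":
        pacemakers = tuple(
            models.PacemakerParams(**{f: float(raw["pacemakers"][n][f])
                                      for f in _PACEMAKER_FIELDS})
            for n in models.PACEMAKERS)
        muscles = tuple(
            models.MuscleParams(**{f: float(raw["muscles"][n][f])
                                   for f in _MUSCLE_FIELDS})
            for n in models.MUSCLES)
        alphas = {lead: tuple(float(w) for w in ws)
                  for lead, ws in raw["alphas"].items()}
        z0_leads = {lead: float(v)
                    for lead, v in raw.get("z0_leads", {}).items()}
        return models.HeterogeneousParams(
            pacemakers=pacemakers, muscles=muscles, z0=float(raw["z0"]),
            alphas=alphas, z0_leads=z0_leads)
    if model == "reaction_diffusion":
        return models.ReactionDiffusionParams(
            H=float(raw["H"]), C=float(raw["C"]), beta=float(raw["beta"]),
            K1=float(raw["K1"]), K2=float(raw["K2"]), K3=float(raw["K3"]),
            K4=float(raw["K4"]), Gamma_t=float(time_scale))
    if model == "ring":
        nodes = {n: models.RingNodeParams(
            **{f: float(raw["nodes"][n][f]) for f in _RING_NODE_FIELDS})
            for n in models.PACEMAKERS}
        couplings = {c: models.RingCoupling(
            k=float(raw["couplings"][c]["k"]),
            tau=float(raw["couplings"][c]["tau"]))
            for c in models.RING_COUPLINGS}
        return models.RingParams(
            nodes=nodes, couplings=couplings,
            alpha0=float(raw["alpha0"]), alpha1=float(raw["alpha1"]),
            alpha3=float(raw["alpha3"]), alpha5=float(raw["alpha5"]),
            beta_G=float(raw["beta_G"]), beta_T=float(time_scale))
    if model == "quasi_periodic":
        kernels = {name: models.GaussianKernel(
            a=float(raw["kernels"][name][0]),
            b=float(raw["kernels"][name][1]),
            theta=parse_angle(raw["kernels"][name][2]))
            for name in models.KERNELS}
        kwargs: dict[str, Any] = {
            "A": float(raw.get("A", 0.005)),
            "fr": float(raw.get("fr", 0.25)),
        }
        if raw.get("tachogram") is not None:
            kwargs["tachogram"] = TachogramSpec(**raw["tachogram"])
        else:
            kwargs["omega"] = 2.0 * math.pi * float(raw["heart_rate"]) / 60.0
        return models.QuasiPeriodicParams(kernels=kernels, **kwargs)
    raise ValueError(f"unknown model {model!r}; choose from {models.MODELS}")


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_registry_cache: dict | None = None


def _registry() -> dict:
    global _registry_cache
    if _registry_cache is None:
        text = (resources.files("ecgsim") / "data" / "presets.json").read_text()
        _registry_cache = json.loads(text)
    return _registry_cache


def _set_path(target: dict, path: str, value) -> None:
    keys = path.split(".")
    node = target
    for key in keys[:-1]:
        node = node.setdefault(key, {})
    if value is None:
        node.pop(keys[-1], None)
    else:
        node[keys[-1]] = copy.deepcopy(value)


def _resolve(model: str, rhythm: str) -> dict:
    """Merged raw entry with base + overrides applied."""
    reg = _registry()
    if model not in reg:
        raise PresetError(
            f"unknown model {model!r}; valid models: {', '.join(reg)}")
    entries = reg[model]
    if rhythm not in entries:
        raise PresetError(
            f"unknown rhythm {rhythm!r} for model {model!r}; valid rhythms: "
            f"{', '.join(entries)}")
    entry = entries[rhythm]
    if "base" in entry:
        base = _resolve(model, entry["base"])
        params = copy.deepcopy(base["params"])
        for path, value in entry.get("overrides", {}).items():
            _set_path(params, path, value)
        merged = {
            "params": params,
            "time_scale": entry.get("time_scale", base["time_scale"]),
            "gain": entry.get("gain", base["gain"]),
            "notes": entry.get("notes", ""),
            "base": entry["base"],
            "overrides": tuple(entry.get("overrides", {})),
        }
        return merged
    return {
        "params": copy.deepcopy(entry["params"]),
        "time_scale": entry.get("time_scale", 1.0),
        "gain": entry.get("gain", 1.0),
        "notes": entry.get("notes", ""),
        "base": None,
        "overrides": (),
    }


def preset_raw(model: str, rhythm: str) -> dict:
    """Deep copy of the fully merged raw parameter dict of one preset."""
    return copy.deepcopy(_resolve(model, rhythm)["params"])


def get_preset(model: str, rhythm: str) -> RhythmPreset:
    """Return a freshly built, immutable preset for ``(model, rhythm)``."""
    entry = _resolve(model, rhythm)
    params = build_params(model, entry["params"], entry["time_scale"])
    return RhythmPreset(model=model, rhythm=rhythm, params=params,
                        time_scale=float(entry["time_scale"]),
                        gain=float(entry["gain"]), notes=entry["notes"],
                        base=entry["base"], overrides=entry["overrides"])


def list_presets() -> list[tuple[str, str, str]]:
    """Deterministic catalog of (model, rhythm, notes) triples."""
    out = []
    for model in models.MODELS:
        for rhythm in _registry().get(model, {}):
            out.append((model, rhythm, _resolve(model, rhythm)["notes"]))
    return out


def validate_preset(raw) -> RhythmPreset | ValidationReport:
    """Validate a serialized preset object.

    ``raw`` must be a mapping with fields ``model``, ``rhythm``, ``params``
    and optionally ``time_scale``, ``gain``, ``notes``.  Returns the built
    :class:`RhythmPreset` when everything checks out, otherwise a
    :class:`ValidationReport` listing every violation.
    """
    issues: list[ValidationIssue] = []
    model = raw.get("model")
    if model not in models.MODELS:
        issues.append(ValidationIssue(
            "model", f"unknown model {model!r}; valid: {models.MODELS}"))
        return ValidationReport(tuple(issues))
    params = raw.get("params")
    if not isinstance(params, Mapping):
        issues.append(ValidationIssue("params", "missing parameter mapping"))
        return ValidationReport(tuple(issues))
    _VALIDATORS[model](params, issues)
    time_scale = raw.get("time_scale", 1.0)
    if not (isinstance(time_scale, (int, float)) and time_scale > 0
            and math.isfinite(time_scale)):
        issues.append(ValidationIssue("time_scale", "must be positive"))
    gain = raw.get("gain", 1.0)
    if not (isinstance(gain, (int, float))
            and GAIN_RANGE[0] <= gain <= GAIN_RANGE[1]):
        issues.append(ValidationIssue(
            "gain", f"must lie in [{GAIN_RANGE[0]}, {GAIN_RANGE[1]}] mV, "
                    f"got {gain!r}"))
    if issues:
        return ValidationReport(tuple(issues))
    try:
        built = build_params(model, params, time_scale)
    except (ValueError, KeyError, TypeError) as err:
        return ValidationReport((ValidationIssue("params", str(err)),))
    return RhythmPreset(model=model, rhythm=str(raw.get("rhythm", "custom")),
                        params=built, time_scale=float(time_scale),
                        gain=float(gain), notes=str(raw.get("notes", "")))
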