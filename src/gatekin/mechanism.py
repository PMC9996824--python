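"""Microscopic rate constants of the minimal reductive-half-reaction scheme.

The scheme is

    E_ox + S  <--k1/k2-->  E_ox:S  --k3 (=kred)-->  E_red:P  --k5-->  E_red + P

with k4 the reverse of flavin reduction (measured as the saturation
intercept krev, typically indistinguishable from zero).  The measurable
steady-state and transient parameters relate to the microscopic constants
through

    kcat     = k3 k5 / (k3 + k4 + k5)
    kcat/Km  = k1 k3 / (k2 + k3)
    kred/Kd  = k1 k3 / k2            (rapid equilibrium, Kd = k2 / k1)
    1/k1     = 1/(kcat/Km) - 1/(kred/Kd)

so measuring kcat, kcat/Km, kred (= k3) and kred/Kd fixes k5, k1 and k2
algebraically.  Uncertainties are propagated either first-order (delta
method) or by Monte Carlo over truncated Gaussian draws of the inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MeasuredParameters",
    "RateConstantSet",
    "MechanismComparison",
    "InfeasibleParametersError",
    "PropagationError",
    "derive_k5",
    "derive_k1",
    "derive_k2",
    "derive_rate_constants",
    "propagate_uncertainty",
    "consistency_check",
    "compare_mechanisms",
    "round_sig",
    "I335H_MEASURED",
    "WILD_TYPE_MEASURED",
]


class InfeasibleParametersError(ValueError):
    """Measured parameters violate a feasibility inequality of the scheme."""


class PropagationError(RuntimeError):
    """Monte-Carlo propagation failed (too many infeasible draws)."""


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (paper-style reporting)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


@dataclass(frozen=True)
class Value:
    """A scalar with a symmetric 1-sigma uncertainty."""

    value: float
    err: float = 0.0

    def __post_init__(self) -> None:
        if self.err < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass(frozen=True)
class MeasuredParameters:
    """pH-independent measured parameters of one enzyme.

    Units: kcat, kred, krev in 1/s; kcat/Km and kred/Kd in 1/(M s);
    Kd in M (optional, informational).
    """

    kcat: Value
    kcat_over_Km: Value
    kred: Value                      # = k3
    kred_over_Kd: Value
    Kd: Value | None = None
    krev: Value = Value(0.0)         # = k4
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("kcat", "kcat_over_Km", "kred", "kred_over_Kd"):
            if getattr(self, name).value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.krev.value < 0:
            raise ValueError("krev must be >= 0")

    @classmethod
    def from_dict(cls, d: dict, label: str = "") -> "MeasuredParameters":
        def v(name, default=None):
            if name not in d:
                return default
            return Value(float(d[name]), float(d.get(f"{name}_err", 0.0)))

        return cls(
            kcat=v("kcat"),
            kcat_over_Km=v("kcat_over_Km"),
            kred=v("kred"),
            kred_over_Kd=v("kred_over_Kd"),
            Kd=v("Kd"),
            krev=v("krev", Value(0.0)),
            label=label or d.get("label", ""),
        )


#: Measured pH-independent parameters of the variant enzyme with the slow
#: substrate (kcat, kred in 1/s; efficiencies in 1/(M s); Kd in M).
I335H_MEASURED = MeasuredParameters(
    kcat=Value(11.0, 1.0),
    kcat_over_Km=Value(2900.0, 400.0),
    kred=Value(32.0, 6.0),
    kred_over_Kd=Value(24000.0, 3000.0),
    Kd=Value(8.0e-4, 3.0e-4),
    label="I335H",
)

#: Wild-type reference values with the same substrate.
WILD_TYPE_MEASURED = MeasuredParameters(
    kcat=Value(100.0, 15.0),
    kcat_over_Km=Value(11000.0, 1500.0),
    kred=Value(133.0, 5.0),
    kred_over_Kd=Value(12000.0, 1200.0),
    Kd=Value(3.5e-3, 3.0e-4),
    label="wild-type",
)


def _delta_err(fn, values: np.ndarray, errs: np.ndarray) -> float:
    """First-order (delta-method) error of fn(values) with independent
    Gaussian inputs, via central finite differences."""
    if not np.any(errs > 0):
        return 0.0
    var = 0.0
    for i, (v, e) in enumerate(zip(values, errs)):
        if e == 0:
            continue
        h = 1e-6 * max(abs(v), 1e-12)
        up, dn = values.copy(), values.copy()
        up[i] += h
        dn[i] -= h
        grad = (fn(up) - fn(dn)) / (2 * h)
        var += (grad * e) ** 2
    return float(np.sqrt(var))


def derive_k5(m: MeasuredParameters) -> Value:
    """Product-release rate constant from kcat = k3 k5 / (k3 + k4 + k5):

        k5 = kcat (k3 + k4) / (k3 - kcat)

    requiring k3 > kcat (turnover cannot exceed the chemical step).
    """
    kcat, k3, k4 = m.kcat.value, m.kred.value, m.krev.value
    if k3 <= kcat:
        raise InfeasibleParametersError(
            f"k5 undefined: requires kred > kcat but kred = {k3:g} <= kcat = {kcat:g}"
        )

    def fn(x):
        return x[0] * (x[1] + x[2]) / (x[1] - x[0])

    vals = np.array([kcat, k3, k4])
    errs = np.array([m.kcat.err, m.kred.err, m.krev.err])
    return Value(fn(vals), _delta_err(fn, vals, errs))


def derive_k1(m: MeasuredParameters) -> Value:
    """Substrate-association rate constant:

        1/k1 = 1/(kcat/Km) - 1/(kred/Kd)

    requiring kred/Kd > kcat/Km (capture efficiency is bounded by the
    transient efficiency).
    """
    eff_ss, eff_tr = m.kcat_over_Km.value, m.kred_over_Kd.value
    if eff_tr <= eff_ss:
        raise InfeasibleParametersError(
            "k1 undefined: requires kred/Kd > kcat/Km but "
            f"kred/Kd = {eff_tr:g} <= kcat/Km = {eff_ss:g}"
        )

    def fn(x):
        return 1.0 / (1.0 / x[0] - 1.0 / x[1])

    vals = np.array([eff_ss, eff_tr])
    errs = np.array([m.kcat_over_Km.err, m.kred_over_Kd.err])
    return Value(fn(vals), _delta_err(fn, vals, errs))


def derive_k2(m: MeasuredParameters, k1: Value | float) -> Value:
    """ES-dissociation rate constant from kred/Kd = k1 k3 / k2
    (rapid equilibrium, Kd = k2/k1):  k2 = k1 k3 / (kred/Kd)."""
    k1v = k1.value if isinstance(k1, Value) else float(k1)
    k1e = k1.err if isinstance(k1, Value) else 0.0
    if k1v <= 0:
        raise InfeasibleParametersError("k2 needs k1 > 0")

    def fn(x):
        return x[0] * x[1] / x[2]

    vals = np.array([k1v, m.kred.value, m.kred_over_Kd.value])
    errs = np.array([k1e, m.kred.err, m.kred_over_Kd.err])
    return Value(fn(vals), _delta_err(fn, vals, errs))


@dataclass
class RateConstantSet:
    """Microscopic rate constants k1..k5 for one enzyme.

    k1 in 1/(M s); k2..k5 in 1/s.  ``provenance`` records whether each
    constant was measured directly or derived through the scheme;
    ``measured`` keeps the inputs for consistency checks.
    """

    k1: Value
    k2: Value
    k3: Value
    k4: Value
    k5: Value
    provenance: dict = field(default_factory=dict)
    measured: MeasuredParameters | None = None
    n_infeasible_draws: int = 0
    label: str = ""

    def as_dict(self, sig: int | None = None) -> dict:
        out = {}
        for name in ("k1", "k2", "k3", "k4", "k5"):
            v: Value = getattr(self, name)
            val = round_sig(v.value, sig) if sig else v.value
            out[name] = {"value": val, "err": v.err,
                         "provenance": self.provenance.get(name, "derived")}
        return out


def derive_rate_constants(m: MeasuredParameters) -> RateConstantSet:
    """Full deterministic derivation of k1, k2, k5 from the measured set,
    with first-order error propagation."""
    k5 = derive_k5(m)
    k1 = derive_k1(m)
    k2 = derive_k2(m, k1)
    return RateConstantSet(
        k1=k1,
        k2=k2,
        k3=m.kred,
        k4=m.krev,
        k5=k5,
        provenance={
            "k1": "derived",
            "k2": "derived",
            "k3": "measured (kred)",
            "k4": "measured (krev)",
            "k5": "derived",
        },
        measured=m,
        label=m.label,
    )


def propagate_uncertainty(
    m: MeasuredParameters,
    n_draws: int = 100_000,
    seed: int | None = 0,
) -> RateConstantSet:
    """Monte-Carlo propagation of measured uncertainties to k1, k2, k5.

    Inputs are drawn from independent Gaussians truncated at zero;
    infeasible draws (violating kred > kcat or kred/Kd > kcat/Km) are
    discarded and counted.  Reported central values are medians, and the
    uncertainty is the central-68% half-width.  Fails if more than half
    of the draws are infeasible.
    """
    rng = np.random.default_rng(seed)

    def draw(v: Value) -> np.ndarray:
        if v.err == 0:
            return np.full(n_draws, v.value)
        x = rng.normal(v.value, v.err, size=n_draws)
        bad = x <= 0
        while bad.any():
            x[bad] = rng.normal(v.value, v.err, size=int(bad.sum()))
            bad = x <= 0
        return x

    kcat = draw(m.kcat)
    eff_ss = draw(m.kcat_over_Km)
    k3 = draw(m.kred)
    eff_tr = draw(m.kred_over_Kd)
    k4 = (
        np.full(n_draws, m.krev.value)
        if m.krev.err == 0
        else np.clip(rng.normal(m.krev.value, m.krev.err, size=n_draws), 0.0, None)
    )
    feasible = (k3 > kcat) & (eff_tr > eff_ss)
    n_bad = int(n_draws - feasible.sum())
    if n_bad > n_draws / 2:
        raise PropagationError(
            f"{n_bad}/{n_draws} Monte-Carlo draws violate the scheme "
            "feasibility inequalities (kred > kcat, kred/Kd > kcat/Km)"
        )
    kcat, eff_ss, k3, eff_tr, k4 = (
        a[feasible] for a in (kcat, eff_ss, k3, eff_tr, k4)
    )
    k5 = kcat * (k3 + k4) / (k3 - kcat)
    k1 = 1.0 / (1.0 / eff_ss - 1.0 / eff_tr)
    k2 = k1 * k3 / eff_tr

    def summarize(x: np.ndarray) -> Value:
        lo, med, hi = np.percentile(x, [16.0, 50.0, 84.0])
        return Value(float(med), float((hi - lo) / 2.0))

    return RateConstantSet(
        k1=summarize(k1),
        k2=summarize(k2),
        k3=summarize(k3),
        k4=Value(float(np.median(k4)), float(np.std(k4))),
        k5=summarize(k5),
        provenance={
            "k1": "derived (Monte Carlo)",
            "k2": "derived (Monte Carlo)",
            "k3": "measured (kred)",
            "k4": "measured (krev)",
            "k5": "derived (Monte Carlo)",
        },
        measured=m,
        n_infeasible_draws=n_bad,
        label=m.label,
    )


def consistency_check(r: RateConstantSet) -> dict:
    """Recompute the measurable parameters from the microscopic constants.

    Returns the recomputed kcat/Km = k1 k3/(k2 + k3),
    kcat = k3 k5/(k3 + k4 + k5) and Kd = k2/k1, with relative deviations
    from the measured values where those are attached.
    """
    k1, k2, k3, k4, k5 = (getattr(r, n).value for n in ("k1", "k2", "k3", "k4", "k5"))
    recomputed = {
        "kcat_over_Km": k1 * k3 / (k2 + k3),
        "kcat": k3 * k5 / (k3 + k4 + k5),
        "Kd": k2 / k1,
    }
    report = {"recomputed": recomputed, "relative_deviation": {}}
    if r.measured is not None:
        m = r.measured
        targets = {
            "kcat_over_Km": m.kcat_over_Km.value,
            "kcat": m.kcat.value,
            "Kd": m.Kd.value if m.Kd is not None else None,
        }
        for name, measured in targets.items():
            if measured is None:
                continue
            report["relative_deviation"][name] = (
                recomputed[name] - measured
            ) / measured
    return report


@dataclass
class MechanismComparison:
    """Fold changes (reference / variant) per microscopic rate constant."""

    folds: dict          # {k name: raw ratio}
    folds_2sf: dict      # {k name: ratio to 2 significant figures}
    direction: dict      # {k name: "decrease" | "increase" | "unchanged"}
    significant: dict    # {k name: bool, from propagated intervals}


def compare_mechanisms(
    wt: RateConstantSet, var: RateConstantSet
) -> MechanismComparison:
    """Per-constant fold change reference/variant with significance from
    the propagated 1-sigma intervals of the log-ratio."""
    folds, folds_2sf, direction, significant = {}, {}, {}, {}
    for name in ("k1", "k2", "k3", "k4", "k5"):
        a: Value = getattr(wt, name)
        b: Value = getattr(var, name)
        if b.value == 0 or a.value == 0:
            continue
        ratio = a.value / b.value
        folds[name] = ratio
        folds_2sf[name] = round_sig(ratio, 2)
        direction[name] = (
            "decrease" if ratio > 1 else "increase" if ratio < 1 else "unchanged"
        )
        rel = math.sqrt(
            (a.err / a.value) ** 2 + (b.err / b.value) ** 2
        )
        significant[name] = abs(math.log(ratio)) > rel
    return MechanismComparison(
        folds=folds, folds_2sf=folds_2sf, direction=direction, significant=significant
    )
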