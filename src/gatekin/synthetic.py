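"""Seeded synthetic trajectories and kinetic datasets with known ground truth.

The trajectory generator emulates a two-state (open/closed) gated protein:
a latent Markov chain switches the gate residue between two basins of the
gate--probe distance, residue--residue contacts are toggled per frame with
designed probabilities, and every other atom jitters around a fixed site.
The kinetic generators invert the four analysis models (single-exponential
transient, hyperbolic saturation, Michaelis--Menten, one-/two-pKa pH
profiles) and add relative Gaussian noise.

Defaults mirror the study conditions the package reproduces: a gate whose
closed basin sits near 5 A and open basin near 16 A (so the 7 A / 14 A
classification thresholds fall between them), 5% relative measurement
noise, stopped-flow substrate concentrations of 0.2--2.5 mM, and a pH grid
of 7.5--10.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trajectory import Topology, Trajectory

__all__ = [
    "SyntheticTrajectorySpec",
    "SyntheticKineticsSpec",
    "StateLabels",
    "SpecError",
    "generate_two_state_trajectory",
    "generate_kinetic_dataset",
    "wild_type_like_spec",
    "variant_like_spec",
    "exponential_trace",
    "hyperbolic_kobs",
    "michaelis_menten_rate",
    "ph_profile_value",
]

CLOSED, OPEN = "closed", "open"

#: lattice spacing between residue sites (A); large enough that only
#: designed contacts fall under the 4.5 A cutoff
_SITE_SPACING = 10.0
#: offset of the probe residue from the lattice along +x
_PROBE_OFFSET = 50.0
#: half-separation of the two satellite atoms of a formed designed contact
_CONTACT_HALF_GAP = 0.75


class SpecError(ValueError):
    """A synthetic-data spec is invalid or geometrically infeasible."""


@dataclass(frozen=True)
class StateLabels:
    """Per-frame latent gating state; ground truth for recovery tests."""

    labels: np.ndarray  # (n_frames,) of "closed"/"open"

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))

    def __len__(self) -> int:
        return self.labels.size

    @property
    def closed_fraction(self) -> float:
        return float(np.mean(self.labels == CLOSED))

    @property
    def open_fraction(self) -> float:
        return float(np.mean(self.labels == OPEN))


@dataclass
class SyntheticTrajectorySpec:
    """Parameters of the two-state gated-trajectory generator.

    ``designed_contact_edges`` maps residue pairs to a target contact
    probability for this condition; pairs with probability 1.0 form the
    rigid scaffold, fractional probabilities produce dynamic contacts.
    """

    n_residues: int = 30
    gate_residue: int = 29
    probe_residue: int = 28
    closed_distance_mean: float = 5.0
    closed_distance_sd: float = 0.6
    open_distance_mean: float = 16.0
    open_distance_sd: float = 0.8
    occupancy_closed: float = 0.5
    switch_probability: float = 0.1
    n_frames: int = 2000
    designed_contact_edges: dict = field(default_factory=dict)  # {(i, j): pc}
    jitter_sd: float = 0.15
    condition_label: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.occupancy_closed < 1.0:
            raise SpecError("occupancy_closed must lie strictly in (0, 1)")
        if self.closed_distance_mean >= self.open_distance_mean:
            raise SpecError("closed distance mean must be below open mean")
        if self.n_frames < 100:
            raise SpecError("n_frames must be >= 100")
        if not 0.0 <= self.switch_probability <= 1.0:
            raise SpecError("switch_probability must be a probability")
        if self.closed_distance_mean - 3 * self.closed_distance_sd < 2.0:
            raise SpecError(
                "closed-distance distribution reaches below the 2 A steric minimum"
            )
        if self.gate_residue == self.probe_residue:
            raise SpecError("gate and probe residues must differ")
        for (i, j), pc in self.designed_contact_edges.items():
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues) or i == j:
                raise SpecError(f"designed contact edge ({i}, {j}) out of range")
            if not 0.0 <= pc <= 1.0:
                raise SpecError(f"designed pc for ({i}, {j}) must be in [0, 1]")
            if self.gate_residue in (i, j) or self.probe_residue in (i, j):
                raise SpecError("designed contact edges may not involve gate/probe")


# fixed intra-residue heavy-atom offsets (A); one hydrogen exercises the
# heavy-atom filters downstream
_BACKBONE_OFFSETS = {
    "N": np.array([0.7, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([-0.5, 0.5, 0.0]),
    "O": np.array([-0.5, -0.5, 0.3]),
    "HA": np.array([0.0, 0.0, 1.0]),
}


def _residue_sites(spec: SyntheticTrajectorySpec) -> np.ndarray:
    """Fixed residue centres: a coarse cubic lattice, with the probe pushed
    out along +x and the gate placed on the probe's +x axis (state-dependent)."""
    sites = np.zeros((spec.n_residues, 3))
    slot = 0
    for r in range(spec.n_residues):
        if r in (spec.gate_residue, spec.probe_residue):
            continue
        sites[r] = (
            _SITE_SPACING * (slot % 4),
            _SITE_SPACING * ((slot // 4) % 4),
            _SITE_SPACING * (slot // 16),
        )
        slot += 1
    sites[spec.probe_residue] = (_PROBE_OFFSET, 0.0, 0.0)
    # gate site is a placeholder; per-frame position set from the latent state
    sites[spec.gate_residue] = (_PROBE_OFFSET + spec.open_distance_mean, 0.0, 0.0)
    return sites


def _markov_states(spec: SyntheticTrajectorySpec, rng: np.random.Generator) -> np.ndarray:
    """Two-state chain with stationary closed occupancy = occupancy_closed.

    Transition probabilities p(closed->open) = s*(1-pi) and
    p(open->closed) = s*pi share the overall switching scale s, so the
    stationary distribution is (pi, 1-pi) for any s > 0.
    """
    pi = spec.occupancy_closed
    s = spec.switch_probability
    p_co = s * (1.0 - pi)   # closed -> open
    p_oc = s * pi           # open -> closed
    states = np.empty(spec.n_frames, dtype=object)
    if s == 0.0:
        states[:] = CLOSED
        return states
    current = CLOSED if rng.random() < pi else OPEN
    u = rng.random(spec.n_frames)
    for t in range(spec.n_frames):
        states[t] = current
        flip = u[t] < (p_co if current == CLOSED else p_oc)
        if flip:
            current = OPEN if current == CLOSED else CLOSED
    return states


def generate_two_state_trajectory(
    spec: SyntheticTrajectorySpec,
) -> tuple[Trajectory, StateLabels]:
    """Generate a gated two-state trajectory with known latent states.

    The gate residue is translated rigidly along a fixed axis from the
    probe residue, so the gate CA -- probe CA distance equals the sampled
    state-conditional Gaussian draw exactly (gate and probe are exempt
    from positional jitter).  Each designed contact is realised by a pair
    of satellite heavy atoms, one per residue, that meet at a rendezvous
    site unique to that residue pair in a Bernoulli-chosen subset of
    frames; rendezvous sites are far from every residue site, so designed
    contacts never induce spurious third-party contacts.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng_state, rng_dist, rng_contact, rng_jitter = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    states = _markov_states(spec, rng_state)
    closed_mask = states == CLOSED

    # state-conditional gate-probe distances
    d = np.where(
        closed_mask,
        rng_dist.normal(spec.closed_distance_mean, spec.closed_distance_sd, spec.n_frames),
        rng_dist.normal(spec.open_distance_mean, spec.open_distance_sd, spec.n_frames),
    )
    d = np.clip(d, 2.0, None)

    sites = _residue_sites(spec)
    edges = sorted(spec.designed_contact_edges.items())

    atom_names, res_idx, res_names = [], [], []
    base_offsets = []  # offset from residue site, per atom
    satellite_atoms = {}  # (i, j) -> (atom index on i, atom index on j)
    for r in range(spec.n_residues):
        for name, off in _BACKBONE_OFFSETS.items():
            atom_names.append(name)
            res_idx.append(r)
            res_names.append("GLY")
            base_offsets.append(off)
        n_sat = 0
        for (i, j), _pc in edges:
            if r in (i, j):
                idx = len(atom_names)
                pair = satellite_atoms.setdefault((i, j), [None, None])
                pair[0 if r == i else 1] = idx
                n_sat += 1
                atom_names.append(f"SG{n_sat}")
                res_idx.append(r)
                res_names.append("GLY")
                base_offsets.append(np.zeros(3))
    base_offsets = np.asarray(base_offsets)
    res_idx = np.asarray(res_idx)

    base = sites[res_idx] + base_offsets  # (n_atoms, 3)
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)

    # per-frame gate placement along +x from the probe
    gate_atoms = np.flatnonzero(res_idx == spec.gate_residue)
    probe_ca = sites[spec.probe_residue]
    gate_centres = probe_ca[None, :] + np.outer(d, np.array([1.0, 0.0, 0.0]))
    coords[:, gate_atoms, :] = (
        gate_centres[:, None, :] + base_offsets[gate_atoms][None, :, :]
    )

    # designed contacts: the pair's two satellites meet at a rendezvous
    # site (one per edge, on the -x/-y side, >=20 A from every residue)
    for k, ((i, j), pc) in enumerate(edges):
        a_i, a_j = satellite_atoms[(i, j)]
        formed = rng_contact.random(spec.n_frames) < pc
        meet = np.array([-20.0 - _SITE_SPACING * (k % 8),
                         -20.0 - _SITE_SPACING * (k // 8), 0.0])
        coords[:, a_i, :] = np.where(
            formed[:, None], meet + [0.0, 0.0, _CONTACT_HALF_GAP], sites[i]
        )
        coords[:, a_j, :] = np.where(
            formed[:, None], meet - [0.0, 0.0, _CONTACT_HALF_GAP], sites[j]
        )

    # jitter everything except gate and probe residues (keeps the gate
    # distance exact by construction)
    jitter_mask = ~np.isin(res_idx, [spec.gate_residue, spec.probe_residue])
    jitter = rng_jitter.normal(
        0.0, spec.jitter_sd, size=(spec.n_frames, int(jitter_mask.sum()), 3)
    )
    coords[:, jitter_mask, :] += jitter

    topo = Topology(
        atom_names=np.asarray(atom_names, dtype=object),
        residue_indices=res_idx,
        residue_names=np.asarray(res_names, dtype=object),
    )
    traj = Trajectory(
        coordinates=coords,
        topology=topo,
        condition_label=spec.condition_label,
    )
    return traj, StateLabels(labels=states)


# shared scaffold (pc = 1 in both conditions): two clique-like domains
# bridged by a single edge, so the consensus network has a clear
# two-community structure
_SCAFFOLD_EDGES = (
    [(i, j) for i in range(0, 6) for j in range(i + 1, 6) if j - i >= 3]
    + [(i, j) for i in range(6, 12) for j in range(i + 1, 12) if j - i >= 3]
    + [(5, 8)]
)

#: dynamic contacts (pair -> (pc wild-type-like, pc variant-like)); the
#: variant-like condition forms inter-domain contacts more often, emulating
#: a shift toward the closed conformation
_DYNAMIC_EDGES = {
    (0, 9): (0.20, 0.90),
    (1, 10): (0.30, 0.85),
    (2, 11): (0.25, 0.80),
    (3, 9): (0.70, 0.20),
    (13, 17): (0.50, 0.50),
}


def occupancy_standard_error(spec: SyntheticTrajectorySpec) -> float:
    """Sampling standard error of the empirical closed fraction.

    For a two-state Markov chain with switching scale ``s`` the
    lag-1 autocorrelation of the state indicator is ``rho = 1 - s`` and

        var(fraction) ~= pi (1 - pi) / n * (1 + rho) / (1 - rho),

    the binomial variance inflated by the integrated autocorrelation time.
    """
    pi = spec.occupancy_closed
    s = spec.switch_probability
    if s <= 0:
        return float("inf")
    rho = max(0.0, 1.0 - s)
    return float(
        np.sqrt(pi * (1 - pi) / spec.n_frames * (1 + rho) / max(1 - rho, 1e-12))
    )


def wild_type_like_spec(seed: int = 0, n_frames: int = 2000) -> SyntheticTrajectorySpec:
    """Reference condition: gate open and closed roughly equally often."""
    edges = {e: 1.0 for e in _SCAFFOLD_EDGES}
    edges.update({k: v[0] for k, v in _DYNAMIC_EDGES.items()})
    return SyntheticTrajectorySpec(
        occupancy_closed=0.5,
        designed_contact_edges=edges,
        condition_label="wild-type-like",
        n_frames=n_frames,
        seed=seed,
    )


def variant_like_spec(seed: int = 1, n_frames: int = 2000) -> SyntheticTrajectorySpec:
    """Variant condition: occupancy shifted toward the closed state."""
    edges = {e: 1.0 for e in _SCAFFOLD_EDGES}
    edges.update({k: v[1] for k, v in _DYNAMIC_EDGES.items()})
    return SyntheticTrajectorySpec(
        occupancy_closed=0.8,
        designed_contact_edges=edges,
        condition_label="variant-like",
        n_frames=n_frames,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# kinetic generators
# ---------------------------------------------------------------------------

def exponential_trace(t, kobs, B, C):
    """Single-exponential flavin-reduction transient A(t) = B e^(-kobs t) + C."""
    t = np.asarray(t, dtype=float)
    return B * np.exp(-kobs * t) + C


def hyperbolic_kobs(S, kred, Kd, krev=0.0):
    """Hyperbolic saturation kobs(S) = kred S / (Kd + S) + krev."""
    S = np.asarray(S, dtype=float)
    return kred * S / (Kd + S) + krev


def michaelis_menten_rate(S, kcat, Km):
    """Michaelis-Menten initial rate v/[E] = kcat S / (Km + S)."""
    S = np.asarray(S, dtype=float)
    return kcat * S / (Km + S)


def ph_profile_value(pH, C, pKa, n_pka=1):
    """pH profile rising with slope +1 (n_pka=1) or +2 (two indistinguishable
    pKa values, n_pka=2) toward the pH-independent limit C."""
    pH = np.asarray(pH, dtype=float)
    if n_pka == 1:
        return C / (1.0 + 10.0 ** (pKa - pH))
    if n_pka == 2:
        return C / (1.0 + 10.0 ** (pKa - pH) + 10.0 ** (2.0 * (pKa - pH)))
    raise ValueError("n_pka must be 1 or 2")


@dataclass
class SyntheticKineticsSpec:
    """Ground-truth parameters and design grids for the kinetic generators.

    Default parameter values follow the variant enzyme's measured
    constants (kred = 32 1/s, Kd = 0.8 mM, kcat = 11 1/s,
    Km = kcat / (kcat/Km) with kcat/Km = 2900 1/(M s), kred pKa = 9.5);
    default noise is 5% relative Gaussian, the replicate-to-replicate
    scatter of the measurements being emulated.
    """

    # transient trace
    kobs: float = 50.0
    amplitude: float = 0.1
    offset: float = 0.05
    # kobs saturation
    kred: float = 32.0
    Kd: float = 8.0e-4
    krev: float = 0.0
    # steady state
    kcat: float = 11.0
    Km: float = 11.0 / 2900.0
    # pH profile
    ph_limit: float = 32.0
    pKa: float = 9.5
    n_pka: int = 1
    # noise and grids
    noise_sd: float = 0.05  # relative Gaussian
    time_points: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 0.1, 100)
    )
    substrate_concentrations_M: np.ndarray = field(
        default_factory=lambda: np.array([2e-4, 4e-4, 6e-4, 1e-3, 1.5e-3, 2.5e-3])
    )
    ph_values: np.ndarray = field(
        default_factory=lambda: np.linspace(7.5, 10.0, 11)
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("kobs", "kred", "Kd", "kcat", "Km", "ph_limit"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if self.krev < 0:
            raise SpecError("krev must be >= 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if np.any(np.asarray(self.substrate_concentrations_M) <= 0):
            raise SpecError("substrate concentrations must be positive")


_KINDS = ("trace", "saturation", "initial_rates", "ph_profile")


def generate_kinetic_dataset(spec: SyntheticKineticsSpec, kind: str) -> pd.DataFrame:
    """Generate one synthetic kinetic dataset.

    Noise-free values obey the corresponding model exactly; multiplicative
    Gaussian noise of relative sd ``spec.noise_sd`` is then applied.
    """
    spec.validate()
    if kind not in _KINDS:
        raise SpecError(f"unknown dataset kind {kind!r}; expected one of {_KINDS}")
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed).spawn(len(_KINDS))[_KINDS.index(kind)]
    )
    if kind == "trace":
        x = np.asarray(spec.time_points, dtype=float)
        if x.size == 0:
            raise SpecError("empty time grid")
        y = exponential_trace(x, spec.kobs, spec.amplitude, spec.offset)
        cols = {"time_s": x, "A445": _noisy(y, spec.noise_sd, rng)}
    elif kind == "saturation":
        x = np.asarray(spec.substrate_concentrations_M, dtype=float)
        if x.size == 0:
            raise SpecError("empty concentration grid")
        y = hyperbolic_kobs(x, spec.kred, spec.Kd, spec.krev)
        cols = {"S": x, "S_unit": "M", "kobs": _noisy(y, spec.noise_sd, rng)}
    elif kind == "initial_rates":
        x = np.asarray(spec.substrate_concentrations_M, dtype=float)
        if x.size == 0:
            raise SpecError("empty concentration grid")
        y = michaelis_menten_rate(x, spec.kcat, spec.Km)
        cols = {"S": x, "S_unit": "M", "v_over_E": _noisy(y, spec.noise_sd, rng)}
    else:  # ph_profile
        x = np.asarray(spec.ph_values, dtype=float)
        if x.size == 0:
            raise SpecError("empty pH grid")
        y = ph_profile_value(x, spec.ph_limit, spec.pKa, spec.n_pka)
        cols = {"pH": x, "value": _noisy(y, spec.noise_sd, rng)}
    return pd.DataFrame(cols)


def _noisy(y: np.ndarray, rel_sd: float, rng: np.random.Generator) -> np.ndarray:
    if rel_sd == 0.0:
        return y.copy()
    return y * (1.0 + rng.normal(0.0, rel_sd, size=y.shape))
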