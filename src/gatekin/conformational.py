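"""Per-trajectory conformational statistics.

Covers the ensemble-level descriptors of a gated protein: per-residue
RMSF after least-squares superposition, the gate--probe distance series,
three-way open/intermediate/closed state classification, distance
probability densities with the corresponding free-energy profile
F = -kB T ln P, and Cartesian PCA of the coordinate covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import AtomSelection, SelectionError, Trajectory, resolve_selection

__all__ = [
    "DistanceSeries",
    "StateOccupancy",
    "FreeEnergyProfile",
    "RMSFResult",
    "PCAResult",
    "AnalysisError",
    "KB_KCAL_PER_MOL_K",
    "compute_rmsf",
    "distance_series",
    "classify_states",
    "free_energy_profile",
    "pca",
    "superpose",
]

#: Boltzmann constant in kcal/(mol K); kB*T = 0.596 kcal/mol at 300 K
KB_KCAL_PER_MOL_K = 0.0019872041


class AnalysisError(ValueError):
    """Invalid parameters or degenerate inputs for an analysis operation."""


@dataclass
class DistanceSeries:
    """Per-frame distance (A) between two atoms, e.g. the gate tyrosine
    ring carbon and the flavin N5."""

    values: np.ndarray
    atom_pair: tuple = (None, None)
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise AnalysisError("distance series must be one-dimensional")
        if not np.isfinite(self.values).all() or (self.values <= 0).any():
            raise AnalysisError("distances must be positive and finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class StateOccupancy:
    """Closed / intermediate / open occupancy of a gate-distance series."""

    fraction_closed: float
    fraction_intermediate: float
    fraction_open: float
    counts: dict
    closed_max: float
    open_min: float

    @property
    def n_frames(self) -> int:
        return sum(self.counts.values())


@dataclass
class FreeEnergyProfile:
    """Distance histogram density and F = -kB T ln P, offset to min 0.

    Empty bins have NaN free energy (undefined, not zero).
    """

    bin_centers: np.ndarray
    density: np.ndarray
    free_energy: np.ndarray
    temperature: float
    bin_width: float


@dataclass
class RMSFResult:
    """Per-residue RMSF (A), averaged over the selected atoms of each
    residue after superposition."""

    rmsf: np.ndarray                  # (n_residues,) NaN where no selected atom
    per_atom: np.ndarray              # (n_selected_atoms,)
    atom_indices: np.ndarray
    reference: str = "mean structure of the ensemble"


@dataclass
class PCAResult:
    """Cartesian-coordinate PCA of the superposed ensemble."""

    eigenvalues: np.ndarray           # all components, descending (A^2)
    variance_fractions: np.ndarray    # same length, sums to 1
    components: np.ndarray            # (k, 3*n_selected) orthonormal rows
    projections: list                 # per input trajectory, (frames, k)
    mean: np.ndarray                  # (3*n_selected,) reference structure


def _as_selection(traj: Trajectory, selection) -> AtomSelection:
    if selection is None:
        return resolve_selection(traj, "backbone")
    if isinstance(selection, str):
        return resolve_selection(traj, selection)
    return selection


def superpose(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose each frame of ``(F, N, 3)`` onto ``reference``.

    Removes net translation and rotation (Kabsch, via
    scipy ``Rotation.align_vectors``). Needs >=3 non-collinear points.
    """
    ref = reference - reference.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        x = coords[f] - coords[f].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref, x)
        out[f] = rot.apply(x)
    return out


def _superpose_to_mean(coords: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Iteratively superpose frames onto their evolving mean structure."""
    ref = coords[0]
    aligned = coords
    for _ in range(n_iter):
        aligned = superpose(coords, ref)
        ref = aligned.mean(axis=0)
    return aligned


def compute_rmsf(
    traj: Trajectory,
    selection: AtomSelection | str | None = None,
    align: bool = True,
) -> RMSFResult:
    """Per-residue RMSF of the selected atoms (default: backbone).

    Frames are superposed onto the selection's mean structure before the
    fluctuation is measured; each atom's root-mean-square deviation from
    its mean position is then averaged within each residue.
    """
    sel = _as_selection(traj, selection)
    idx = sel.as_array()
    coords = traj.coordinates[:, idx, :]
    if align:
        if idx.size < 3:
            raise AnalysisError("superposition needs at least 3 selected atoms")
        coords = _superpose_to_mean(coords)
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    res_of_atom = traj.topology.residue_indices[idx]
    rmsf = np.full(traj.n_residues, np.nan)
    for r in np.unique(res_of_atom):
        rmsf[r] = per_atom[res_of_atom == r].mean()
    return RMSFResult(rmsf=rmsf, per_atom=per_atom, atom_indices=idx)


def distance_series(
    traj: Trajectory,
    a: AtomSelection | str,
    b: AtomSelection | str,
) -> DistanceSeries:
    """Euclidean distance per frame between two single atoms (no alignment;
    the distance is frame-internal)."""
    sa, sb = _as_selection(traj, a), _as_selection(traj, b)
    if len(sa) != 1 or len(sb) != 1:
        raise SelectionError(
            f"distance_series needs single-atom selections, got {len(sa)} and {len(sb)}"
        )
    ia, ib = sa.indices[0], sb.indices[0]
    diff = traj.coordinates[:, ia, :] - traj.coordinates[:, ib, :]
    return DistanceSeries(
        values=np.linalg.norm(diff, axis=1),
        atom_pair=(ia, ib),
        condition_label=traj.condition_label,
    )


def classify_states(
    series: DistanceSeries,
    closed_max: float = 7.0,
    open_min: float = 14.0,
) -> StateOccupancy:
    """Three-way classification: closed (d <= closed_max),
    open (d >= open_min), intermediate otherwise."""
    if closed_max >= open_min:
        raise AnalysisError(
            f"closed_max ({closed_max}) must be below open_min ({open_min})"
        )
    d = series.values
    n = d.size
    n_closed = int(np.sum(d <= closed_max))
    n_open = int(np.sum(d >= open_min))
    n_mid = n - n_closed - n_open
    return StateOccupancy(
        fraction_closed=n_closed / n,
        fraction_intermediate=n_mid / n,
        fraction_open=n_open / n,
        counts={"closed": n_closed, "intermediate": n_mid, "open": n_open},
        closed_max=closed_max,
        open_min=open_min,
    )


def free_energy_profile(
    series: DistanceSeries,
    bin_width: float = 0.25,
    temperature: float = 300.0,
) -> FreeEnergyProfile:
    """Histogram density of the distance and F = -kB T ln P.

    The free energy is defined on occupied bins only (NaN elsewhere) and
    offset so that its minimum is exactly zero.
    """
    if bin_width <= 0:
        raise AnalysisError("bin_width must be positive")
    if len(series) < 100:
        raise AnalysisError("free-energy profile needs >= 100 frames")
    d = series.values
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    density, _ = np.histogram(d, bins=edges, density=True)
    kt = KB_KCAL_PER_MOL_K * temperature
    with np.errstate(divide="ignore"):
        free = np.where(density > 0, -kt * np.log(density), np.nan)
    free = free - np.nanmin(free)
    return FreeEnergyProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        free_energy=free,
        temperature=temperature,
        bin_width=bin_width,
    )


def pca(
    trajs: Trajectory | list,
    selection: AtomSelection | str | None = None,
    k: int = 2,
    orient_by: np.ndarray | None = None,
    align: bool = True,
) -> PCAResult:
    """Cartesian PCA of one or more trajectories over a shared selection.

    All frames are pooled, superposed on the combined mean structure, and
    the covariance of the flattened coordinates is eigendecomposed.
    Projections are returned per input trajectory so conditions can be
    overlaid.

    The sign of each component is fixed deterministically: if
    ``orient_by`` gives one scalar per pooled frame (e.g. the gate
    distance, so open frames project positive), PC1 is oriented to
    correlate positively with it; otherwise each component's
    largest-magnitude coefficient is made positive.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if k < 2:
        raise AnalysisError("k must be >= 2")
    sel = _as_selection(trajs[0], selection)
    idx = sel.as_array()
    blocks = [t.coordinates[:, idx, :] for t in trajs]
    pooled = np.concatenate(blocks, axis=0)
    if pooled.shape[0] < 3:
        raise AnalysisError("PCA needs at least 3 frames in total")
    aligned = _superpose_to_mean(pooled) if align else pooled
    flat = aligned.reshape(aligned.shape[0], -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / centered.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    comps = evecs[:, :k].T.copy()
    proj_all = centered @ comps.T
    for c in range(k):
        if orient_by is not None and c == 0:
            ref = np.asarray(orient_by, dtype=float)
            if ref.size != proj_all.shape[0]:
                raise AnalysisError(
                    "orient_by must give one value per pooled frame"
                )
            flip = np.corrcoef(proj_all[:, 0], ref)[0, 1] < 0
        else:
            flip = comps[c, np.argmax(np.abs(comps[c]))] < 0
        if flip:
            comps[c] *= -1
            proj_all[:, c] *= -1
    projections = []
    start = 0
    for b in blocks:
        projections.append(proj_all[start : start + b.shape[0]])
        start += b.shape[0]
    return PCAResult(
        eigenvalues=evals,
        variance_fractions=fractions,
        components=comps,
        projections=projections,
        mean=mean,
    )
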