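"""Observables of weighted multi-model structural ensembles.

Handles multi-MODEL PDB ensembles of one or two chains: bias-based
reweighting, heavy-atom contact maps with population statistics,
interface summaries, iteratively superposed RMSF, dihedral-based helix
populations, radii of gyration and 2-D free-energy surfaces.

Coordinates are held in nanometres internally; PDB Angstroms are
converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

#: Dihedral windows (degrees) defining a helical residue.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
HELIX_MIN_RUN = 4


@dataclass
class StructuralEnsemble:
    """A weighted set of conformations sharing one atom topology.

    ``coords`` has shape (n_models, n_atoms, 3) in nm.  ``domains`` maps
    chain ids to domain names (e.g. ``{"A": "CID", "B": "NCBD"}``).
    """

    coords: np.ndarray
    elements: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    weights: np.ndarray | None = None
    domains: dict = field(default_factory=dict)
    res_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        for name in ("elements", "atom_names", "res_ids", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have one entry per atom")
            setattr(self, name, arr)
        if self.weights is None:
            self.weights = np.full(self.n_models, 1.0 / self.n_models)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_models,):
            raise ValueError("need one weight per model")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be a probability vector")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def heavy(self) -> np.ndarray:
        return np.char.upper(self.elements.astype(str)) != "H"

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, res_id) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.res_ids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_atom_indices(self) -> list[np.ndarray]:
        keys = self.residue_keys()
        lookup = {k: i for i, k in enumerate(keys)}
        groups = [[] for _ in keys]
        for a, (c, r) in enumerate(zip(self.chain_ids, self.res_ids)):
            groups[lookup[(str(c), int(r))]].append(a)
        return [np.array(g) for g in groups]

    def residue_domains(self) -> list[str]:
        return [self.domains.get(chain, chain) for chain, _ in self.residue_keys()]

    def with_weights(self, weights: np.ndarray) -> "StructuralEnsemble":
        return StructuralEnsemble(
            self.coords,
            self.elements,
            self.atom_names,
            self.res_ids,
            self.chain_ids,
            weights,
            dict(self.domains),
            self.res_names,
        )

    @classmethod
    def from_pdb(cls, path, weights=None, domains=None) -> "StructuralEnsemble":
        """Read a multi-MODEL PDB file (Angstrom -> nm)."""
        import biotite.structure.io.pdb as pdb

        stack = pdb.PDBFile.read(str(path)).get_structure(model=None)
        return cls(
            coords=np.asarray(stack.coord, dtype=float) / 10.0,
            elements=np.asarray(stack.element),
            atom_names=np.asarray(stack.atom_name),
            res_ids=np.asarray(stack.res_id),
            chain_ids=np.asarray(stack.chain_id),
            weights=weights,
            domains=domains or {},
            res_names=np.asarray(stack.res_name),
        )

    def to_pdb(self, path) -> None:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        n_atoms = self.n_atoms
        array = struc.AtomArray(n_atoms)
        array.element = self.elements.astype(str)
        array.atom_name = self.atom_names.astype(str)
        array.res_id = self.res_ids.astype(int)
        array.chain_id = self.chain_ids.astype(str)
        array.res_name = (
            self.res_names.astype(str)
            if self.res_names is not None
            else np.full(n_atoms, "ALA")
        )
        stack = struc.stack(
            [array] * self.n_models
        )
        stack.coord = self.coords * 10.0
        f = pdb.PDBFile()
        f.set_structure(stack)
        f.write(str(path))


def reweight(bias_values, kt: float) -> np.ndarray:
    """Normalised weights ``w_i ∝ exp(+B_i / kT)`` (max-shifted)."""
    b = np.asarray(bias_values, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("bias values must be finite")
    z = (b - b.max()) / kt
    w = np.exp(z)
    return w / w.sum()


@dataclass
class ContactMap:
    """Symmetric residue-pair contact populations in [0, 1]."""

    populations: np.ndarray
    residues: list
    domains: list

    @property
    def n_residues(self) -> int:
        return self.populations.shape[0]

    def inter_domain_mask(self) -> np.ndarray:
        dom = np.asarray(self.domains)
        return dom[:, None] != dom[None, :]


def contact_map(ens: StructuralEnsemble, cutoff: float = 0.5) -> ContactMap:
    """Weighted residue-residue contact populations.

    Two residues are in contact in a model iff any heavy-atom pair is at
    a distance strictly below ``cutoff`` (nm).  Self-contacts are
    excluded; the population of a pair is the weight of the models in
    which it is formed.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = ens.heavy
    if not heavy.any():
        raise ValueError("ensemble contains no heavy atoms")
    keys = ens.residue_keys()
    lookup = {k: i for i, k in enumerate(keys)}
    atom_res = np.array(
        [lookup[(str(c), int(r))] for c, r in zip(ens.chain_ids, ens.res_ids)]
    )
    heavy_idx = np.flatnonzero(heavy)
    if not all((heavy[g]).any() for g in ens.residue_atom_indices()):
        raise ValueError("hydrogen-only residues cannot form heavy-atom contacts")
    n_res = len(keys)
    pop = np.zeros((n_res, n_res))
    for m in range(ens.n_models):
        xyz = ens.coords[m, heavy_idx]
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
            pairs = pairs[d < cutoff]  # strict inequality at the cutoff
        seen = np.zeros((n_res, n_res), dtype=bool)
        ri = atom_res[heavy_idx[pairs[:, 0]]]
        rj = atom_res[heavy_idx[pairs[:, 1]]]
        keep = ri != rj
        seen[ri[keep], rj[keep]] = True
        seen |= seen.T
        pop += ens.weights[m] * seen
    np.clip(pop, 0.0, 1.0, out=pop)
    return ContactMap(pop, keys, ens.residue_domains())


@dataclass
class InterfaceSummary:
    n_contacts: int
    average_population: float | None
    per_residue_counts: np.ndarray
    per_residue_normalized: np.ndarray
    residues: list


def interface_summary(
    cmap: ContactMap, threshold: float = 0.05, mode: str = "pairs"
) -> InterfaceSummary:
    """Inter-domain contacts populated above ``threshold`` (strict).

    ``mode="pairs"`` counts residue pairs (primary); ``mode="residues"``
    counts residues participating in at least one qualifying contact.
    Per-residue qualifying-contact counts are normalized by their
    maximum across residues.
    """
    if mode not in ("pairs", "residues"):
        raise ValueError("mode must be 'pairs' or 'residues'")
    inter = cmap.inter_domain_mask()
    qual = (cmap.populations > threshold) & inter
    iu = np.triu_indices(cmap.n_residues, k=1)
    qual_pairs = qual[iu]
    pops = cmap.populations[iu][qual_pairs]
    per_res = qual.sum(axis=1).astype(float)
    if mode == "pairs":
        count = int(qual_pairs.sum())
    else:
        count = int((per_res > 0).sum())
    avg = float(pops.mean()) if len(pops) else None
    max_count = per_res.max()
    normalized = per_res / max_count if max_count > 0 else per_res
    return InterfaceSummary(count, avg, per_res, normalized, cmap.residues)


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation of centred ``mobile`` onto centred ``reference``."""
    H = mobile.T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _superpose_calpha(ens: StructuralEnsemble, tol: float = 1e-6, max_iter: int = 100):
    ca = np.flatnonzero(ens.atom_names.astype(str) == "CA")
    if len(ca) == 0:
        raise ValueError("no C-alpha atoms in ensemble")
    X = ens.coords[:, ca, :].copy()
    X -= X.mean(axis=1, keepdims=True)
    w = ens.weights
    mean = np.einsum("m,mij->ij", w, X)
    for _ in range(max_iter):
        for m in range(X.shape[0]):
            X[m] = X[m] @ _kabsch(X[m], mean)
        new_mean = np.einsum("m,mij->ij", w, X)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            break
    return X, mean, ca


def rmsf(ens: StructuralEnsemble) -> np.ndarray:
    """Per-residue C-alpha RMSF (nm) about the weighted mean structure.

    Models are iteratively superposed (weighted Kabsch) onto the
    weighted mean until the mean moves less than 1e-6 nm.
    """
    if ens.n_models < 2:
        raise ValueError("RMSF requires at least two models")
    X, mean, _ = _superpose_calpha(ens)
    dev2 = ((X - mean) ** 2).sum(axis=2)  # (models, n_ca)
    return np.sqrt(np.einsum("m,mi->i", ens.weights, dev2))


def _dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle (degrees) for stacked coordinate arrays."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    return np.degrees(np.arctan2(y, x))


def backbone_dihedrals(ens: StructuralEnsemble):
    """Per-model phi/psi angles (degrees) for every residue.

    Returns ``(phi, psi)`` arrays of shape (n_models, n_residues); chain
    termini and residues with missing backbone atoms are NaN.
    """
    keys = ens.residue_keys()
    idx = {}
    names = ens.atom_names.astype(str)
    for a, (c, r) in enumerate(zip(ens.chain_ids, ens.res_ids)):
        if names[a] in ("N", "CA", "C"):
            idx[(str(c), int(r), names[a])] = a
    n_models, n_res = ens.n_models, len(keys)
    phi = np.full((n_models, n_res), np.nan)
    psi = np.full((n_models, n_res), np.nan)
    skipped = []
    for i, (chain, rid) in enumerate(keys):
        triple = [idx.get((chain, rid, nm)) for nm in ("N", "CA", "C")]
        if any(t is None for t in triple):
            skipped.append((chain, rid))
            continue
        n_i, ca_i, c_i = triple
        c_prev = idx.get((chain, rid - 1, "C"))
        n_next = idx.get((chain, rid + 1, "N"))
        if c_prev is not None:
            phi[:, i] = _dihedral(
                ens.coords[:, c_prev],
                ens.coords[:, n_i],
                ens.coords[:, ca_i],
                ens.coords[:, c_i],
            )
        if n_next is not None:
            psi[:, i] = _dihedral(
                ens.coords[:, n_i],
                ens.coords[:, ca_i],
                ens.coords[:, c_i],
                ens.coords[:, n_next],
            )
    if skipped:
        warnings.warn(
            f"residues skipped for missing backbone atoms: {skipped[:5]}"
            + ("..." if len(skipped) > 5 else ""),
            stacklevel=2,
        )
    return phi, psi


def helix_by_model(ens: StructuralEnsemble) -> np.ndarray:
    """Boolean (n_models, n_residues) helix assignment.

    A residue is helical iff phi in (-100, -30), psi in (-80, -5) and it
    sits in a run of at least four consecutive such residues of the same
    chain.
    """
    phi, psi = backbone_dihedrals(ens)
    with np.errstate(invalid="ignore"):
        in_window = (
            (phi > HELIX_PHI[0])
            & (phi < HELIX_PHI[1])
            & (psi > HELIX_PSI[0])
            & (psi < HELIX_PSI[1])
        )
    chains = np.array([c for c, _ in ens.residue_keys()])
    helical = np.zeros_like(in_window, dtype=bool)
    for chain in np.unique(chains):
        cols = np.flatnonzero(chains == chain)
        sub = in_window[:, cols]
        for m in range(sub.shape[0]):
            run_start = 0
            row = sub[m]
            for j in range(len(row) + 1):
                if j == len(row) or not row[j]:
                    if j - run_start >= HELIX_MIN_RUN:
                        helical[m, cols[run_start:j]] = True
                    run_start = j + 1
    return helical


def helix_profile(ens: StructuralEnsemble) -> tuple[np.ndarray, float]:
    """Weighted per-residue helix population and the average helix fraction."""
    helical = helix_by_model(ens)
    pop = np.einsum("m,mi->i", ens.weights, helical.astype(float))
    return pop, float(pop.mean())


def helix_fraction_per_model(ens: StructuralEnsemble) -> np.ndarray:
    """Fraction of residues assigned helical in each model."""
    return helix_by_model(ens).mean(axis=1)


def radius_of_gyration(ens: StructuralEnsemble) -> np.ndarray:
    """Mass-weighted heavy-atom radius of gyration (nm) per model."""
    heavy = ens.heavy
    masses = np.array(
        [ATOMIC_MASS[str(e).upper()] for e in ens.elements[heavy]], dtype=float
    )
    xyz = ens.coords[:, heavy, :]
    com = np.einsum("a,mai->mi", masses, xyz) / masses.sum()
    dev2 = ((xyz - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt(np.einsum("a,ma->m", masses, dev2) / masses.sum())


@dataclass
class FreeEnergySurface:
    """2-D free-energy grid, min-shifted to zero; empty bins are +inf."""

    free_energy: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    kt: float
    degenerate: bool = False

    @property
    def minimum(self) -> tuple[float, float]:
        """Bin-centre coordinates of the lowest free-energy bin."""
        i, j = np.unravel_index(np.argmin(self.free_energy), self.free_energy.shape)
        return (
            0.5 * (self.x_edges[i] + self.x_edges[i + 1]),
            0.5 * (self.y_edges[j] + self.y_edges[j + 1]),
        )


def fes_2d(
    cv_x,
    cv_y,
    weights,
    bins: int = 32,
    kt: float = 2.48,
    ranges=None,
) -> FreeEnergySurface:
    """Free-energy surface ``F = -kT ln(sum of weights per bin)``.

    The surface is shifted so its minimum is zero; bins without weight
    are unreachable (+inf).  With all weight in a single bin the surface
    is degenerate and flagged.
    """
    if bins < 4:
        raise ValueError("need at least 4 bins per axis")
    hist, x_edges, y_edges = np.histogram2d(
        np.asarray(cv_x, dtype=float),
        np.asarray(cv_y, dtype=float),
        bins=bins,
        range=ranges,
        weights=np.asarray(weights, dtype=float),
    )
    with np.errstate(divide="ignore"):
        F = -kt * np.log(hist)
    F -= F.min()
    degenerate = int(np.sum(hist > 0)) <= 1
    return FreeEnergySurface(F, x_edges, y_edges, kt, degenerate)
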