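"""Seeded synthetic-data generators for every analysis module.

Each generator draws from its own PCG64 stream derived from
``SeedSequence(seed, spawn_key=(stream,))`` so adding a generator never
perturbs existing fixtures; identical recipe + seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denaturation import DenaturationData, TwoStateParams, two_state_curve
from .ensemble_analysis import StructuralEnsemble
from .itc_binding import ITCData, TitrationSchedule, predict_heats
from .metainference_toy import ToySystem
from .phylo_asr import (
    AMINO_ACIDS,
    Alignment,
    Phylogeny,
    SubstitutionModel,
    TransitionKernel,
)

_STREAMS = {"msa": 1, "itc": 2, "denat": 3, "ensemble": 4, "toy": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# sequence evolution


def simulate_msa(
    tree: Phylogeny,
    model: SubstitutionModel,
    length: int,
    seed: int,
    indel_rate: float = 0.0,
) -> tuple[Alignment, dict[str, str]]:
    """Evolve sequences down ``tree`` under ``model``.

    The root is drawn from the equilibrium frequencies; each site is
    assigned a rate category (including the invariant class) and evolved
    per branch through ``P(t * rate)``.  With ``indel_rate > 0`` a
    deletion-only indel process runs on each branch (events per branch
    ~ Poisson(rate * t * length), geometric lengths with mean 2); deleted
    columns are gapped in the affected node and all its descendants.

    Returns the leaf alignment and the true sequence at every node.
    """
    rng = _rng(seed, "msa")
    kernel = TransitionKernel(model)
    rates, probs = model.rate_categories()
    site_cat = rng.choice(len(rates), size=length, p=probs)
    pi = model.frequencies

    root_states = rng.choice(20, size=length, p=pi)
    states = {tree.root.label: root_states}
    presence = {tree.root.label: np.ones(length, dtype=bool)}

    for node in tree.preorder():
        for child in node.children:
            parent_states = states[node.label]
            child_states = parent_states.copy()
            for c in np.unique(site_cat):
                t = child.length * rates[c]
                if t == 0.0:
                    continue
                P = kernel.probability_matrix(t)
                sites = np.flatnonzero(site_cat == c)
                cum = P.cumsum(axis=1)
                u = rng.random(len(sites))
                child_states[sites] = np.array(
                    [
                        np.searchsorted(cum[s], x)
                        for s, x in zip(parent_states[sites], u)
                    ]
                )
            pres = presence[node.label].copy()
            if indel_rate > 0 and child.length > 0:
                n_events = rng.poisson(indel_rate * child.length * length)
                for _ in range(n_events):
                    start = rng.integers(0, length)
                    span = rng.geometric(0.5)  # mean 2
                    pres[start : start + span] = False
            states[child.label] = child_states
            presence[child.label] = pres

    def to_seq(label: str) -> str:
        return "".join(
            AMINO_ACIDS[s] if p else "-"
            for s, p in zip(states[label], presence[label])
        )

    node_sequences = {n.label: to_seq(n.label) for n in tree.preorder()}
    leaves = [n.label for n in tree.leaves]
    aln = Alignment(leaves, [node_sequences[l] for l in leaves])
    return aln, node_sequences


# ---------------------------------------------------------------------------
# calorimetry and denaturation


def simulate_itc(
    n: float,
    kd: float,
    dh: float,
    schedule: TitrationSchedule,
    noise_sd: float,
    seed: int,
    offset: float = 0.0,
) -> ITCData:
    """Wiseman 1:1 isotherm plus i.i.d. Gaussian heat noise (cal)."""
    rng = _rng(seed, "itc")
    heats = predict_heats(n, kd, dh, offset, schedule)
    if noise_sd > 0:
        heats = heats + rng.normal(0.0, noise_sd, size=len(heats))
    return ITCData(heats, schedule)


def simulate_denaturation(
    params: TwoStateParams,
    x: np.ndarray,
    mode: str,
    noise_sd: float,
    seed: int,
    temperature: float | None = None,
) -> DenaturationData:
    """Two-state CD curve plus Gaussian noise."""
    rng = _rng(seed, "denat")
    y = two_state_curve(params, x, mode, temperature)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return DenaturationData(np.asarray(x, dtype=float), y, mode, temperature)


# ---------------------------------------------------------------------------
# structural ensembles

# idealised backbone geometry (Angstrom / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8

HELIX_DIHEDRALS = (-57.0, -47.0)


@dataclass(frozen=True)
class ChainSpec:
    """Plan for one simulated chain: id, length and per-residue helix
    probability (scalar or vector).  Residues with equal consecutive
    probabilities flip between helix and coil as one segment, so the
    realised helix population of a segment of length >= 4 matches its
    probability."""

    chain_id: str
    length: int
    helix_prob: float | np.ndarray = 0.0

    def prob_vector(self) -> np.ndarray:
        p = np.broadcast_to(np.asarray(self.helix_prob, dtype=float), (self.length,))
        if np.any((p < 0) | (p > 1)):
            raise ValueError("helix probabilities must lie in [0, 1]")
        return np.array(p)


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement of a new atom bonded to ``c``."""
    angle = np.radians(angle_deg)
    torsion = -np.radians(torsion_deg)  # sign matches the measured IUPAC dihedral
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone N, CA, C, O coordinates (Angstrom) from dihedrals.

    ``phi[0]`` and ``psi[-1]`` are only used to orient terminal atoms.
    """
    n_res = len(phi)
    coords = np.zeros((n_res, 4, 3))  # N, CA, C, O
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [_BOND_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - _ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + _BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(1, n_res):
        coords[i, 0] = _place_atom(
            coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2],
            _BOND_C_N, _ANGLE_CA_C_N, psi[i - 1],
        )
        coords[i, 1] = _place_atom(
            coords[i - 1, 1], coords[i - 1, 2], coords[i, 0],
            _BOND_N_CA, _ANGLE_C_N_CA, 180.0,  # omega
        )
        coords[i, 2] = _place_atom(
            coords[i - 1, 2], coords[i, 0], coords[i, 1],
            _BOND_CA_C, _ANGLE_N_CA_C, phi[i],
        )
    for i in range(n_res):
        psi_i = psi[i] if i < n_res - 1 else 180.0
        coords[i, 3] = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2],
            _BOND_C_O, _ANGLE_CA_C_O, psi_i + 180.0,
        )
    return coords


def _segments(prob: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of equal helix probability: (start, stop, p)."""
    out = []
    start = 0
    for i in range(1, len(prob) + 1):
        if i == len(prob) or prob[i] != prob[start]:
            out.append((start, i, float(prob[start])))
            start = i
    return out


def simulate_ensemble(
    n_models: int,
    chains: list[ChainSpec],
    noise_nm: float,
    seed: int,
    contact_pair: tuple | None = None,
    contact_distance_nm: float = 0.45,
    separation_nm: float = 1.0,
    domains: dict | None = None,
) -> StructuralEnsemble:
    """Backbone-only two-chain ensembles with known helix statistics.

    Per model, each equal-probability helix segment is set entirely
    helical (ideal alpha dihedrals) or entirely coil (extended-region
    dihedrals).  The second chain is placed either so that the C-alpha
    atoms of ``contact_pair = ((chain_a_res, chain_b_res))`` sit at
    ``contact_distance_nm``, or shifted ``separation_nm`` beyond the
    first chain along x.  Isotropic Gaussian jitter of ``noise_nm`` is
    added to every atom.
    """
    if not 1 <= len(chains) <= 2:
        raise ValueError("supports one or two chains")
    rng = _rng(seed, "ensemble")
    coords_models = []
    meta = None
    for _ in range(n_models):
        chain_coords = []
        all_meta = {"element": [], "name": [], "res_id": [], "chain": []}
        for spec in chains:
            prob = spec.prob_vector()
            phi = np.empty(spec.length)
            psi = np.empty(spec.length)
            for start, stop, p in _segments(prob):
                helical = rng.random() < p
                if helical:
                    phi[start:stop] = HELIX_DIHEDRALS[0]
                    psi[start:stop] = HELIX_DIHEDRALS[1]
                else:
                    phi[start:stop] = rng.uniform(-160.0, -110.0, stop - start)
                    psi[start:stop] = rng.uniform(120.0, 160.0, stop - start)
            bb = _build_backbone(phi, psi) / 10.0  # Angstrom -> nm
            chain_coords.append(bb)
            for i in range(spec.length):
                for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                    all_meta["element"].append(el)
                    all_meta["name"].append(nm)
                    all_meta["res_id"].append(i + 1)
                    all_meta["chain"].append(spec.chain_id)
        if len(chains) == 2:
            a, b = chain_coords
            if contact_pair is not None:
                ra, rb = contact_pair
                target = a[ra - 1, 1] + np.array([contact_distance_nm, 0.0, 0.0])
                b = b + (target - b[rb - 1, 1])
            else:
                shift = a[:, :, 0].max() - b[:, :, 0].min() + separation_nm
                b = b + np.array([shift, 0.0, 0.0])
            chain_coords = [a, b]
        flat = np.concatenate([c.reshape(-1, 3) for c in chain_coords])
        if noise_nm > 0:
            flat = flat + rng.normal(0.0, noise_nm, size=flat.shape)
        coords_models.append(flat)
        if meta is None:
            meta = all_meta
    return StructuralEnsemble(
        coords=np.stack(coords_models),
        elements=np.array(meta["element"]),
        atom_names=np.array(meta["name"]),
        res_ids=np.array(meta["res_id"]),
        chain_ids=np.array(meta["chain"]),
        domains=domains or {},
        res_names=np.full(len(meta["name"]), "ALA"),
    )


# ---------------------------------------------------------------------------
# toy systems


def make_toy_system(name: str, **params) -> ToySystem:
    """Registry of analytic toy systems for the metainference sampler.

    ``double_well_1d``: ``E = a (x^2 - 1)^2`` (a = 8 kJ/mol default).
    ``asym_double_well``: ``E = a (x^2 - 1)^2 + b x``.
    ``harmonic_2d``: ``E = k |x|^2 / 2`` with CVs on both coordinates.
    """
    if name == "double_well_1d":
        a = params.get("a", 8.0)
        return ToySystem(
            name,
            dim=1,
            energy=lambda x: a * (x[0] ** 2 - 1.0) ** 2,
            cvs=[lambda x: x[0]],
            forward_models=[lambda x: x[0]],
            bounds=(-2.5, 2.5),
        )
    if name == "asym_double_well":
        a = params.get("a", 8.0)
        b = params.get("b", 2.0)
        return ToySystem(
            name,
            dim=1,
            energy=lambda x: a * (x[0] ** 2 - 1.0) ** 2 + b * x[0],
            cvs=[lambda x: x[0]],
            forward_models=[lambda x: x[0]],
            bounds=(-2.5, 2.5),
        )
    if name == "harmonic_2d":
        k = params.get("k", 10.0)
        return ToySystem(
            name,
            dim=2,
            energy=lambda x: 0.5 * k * float(np.dot(x, x)),
            cvs=[lambda x: x[0], lambda x: x[1]],
            forward_models=[lambda x: x[0], lambda x: x[1]],
            bounds=(-3.0, 3.0),
        )
    raise KeyError(f"unknown toy system {name!r}")


def free_energy_profile(
    system: ToySystem,
    cv_index: int,
    grid: np.ndarray,
    kt: float,
    mesh_points: int = 20001,
) -> np.ndarray:
    """Reference free energy along one CV by quadrature, min-shifted to 0.

    Integrates the Boltzmann density over the configuration box on a
    dense mesh and bins it by CV value onto ``grid`` (bin centres).
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = system.bounds
    if system.dim == 1:
        mesh = np.linspace(lo, hi, mesh_points)[:, None]
    elif system.dim == 2:
        side = int(np.sqrt(mesh_points))
        g = np.linspace(lo, hi, side)
        mesh = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
    else:
        raise ValueError("quadrature reference supports dims 1 and 2 only")
    E = np.array([system.energy(x) for x in mesh])
    w = np.exp(-(E - E.min()) / kt)
    s = np.array([system.cvs[cv_index](x) for x in mesh])
    edges = np.concatenate(
        [
            [grid[0] - (grid[1] - grid[0]) / 2],
            (grid[1:] + grid[:-1]) / 2,
            [grid[-1] + (grid[-1] - grid[-2]) / 2],
        ]
    )
    hist, _ = np.histogram(s, bins=edges, weights=w)
    with np.errstate(divide="ignore"):
        F = -kt * np.log(hist)
    return F - F[np.isfinite(F)].min()
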