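"""Ground-truth synthetic duplex ensembles.

Analysis code for conformational ensembles is best validated on data whose
answer is known by construction.  This module builds idealized RNA duplexes
(rigid nucleotide fragments on an A-form-like helix, antiparallel strands
related by a C2 rotation) in which every residue's glycosidic torsion chi is
set exactly to a prescribed target, and samples ensembles that mix several
such state templates with Gaussian coordinate noise, dispersed "noise"
frames, and optional Markov-chain state dynamics in pseudo-time.

The geometry is internally consistent rather than stereochemically perfect:
atom names, purine/pyrimidine faces (including the cytosine N4/N3/O2
Watson-Crick atoms) and the chi quadruples are correct, which is all the
torsion, RMSD and hydrogen-bond machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Atom, Residue, Topology, Trajectory, select_atoms, set_symmetry
from .torsion_states import CHI_ATOMS, dihedral
from .ensemble_cluster import symmetry_min_rmsd

__all__ = [
    "EnsembleSpec",
    "StateTemplate",
    "build_duplex",
    "sample_ensemble",
    "markov_labels",
    "gg_loop_spec",
    "gg_survey_trajectory",
    "CHI_SYN",
    "CHI_ANTI",
]

CHI_SYN = 25.0  # deg, center of the conventional syn region
CHI_ANTI = -160.0  # deg, center of the conventional anti region

HELICAL_RISE = 2.81  # A per residue
HELICAL_TWIST = 32.7  # deg per residue
HELIX_RADIUS = 9.4  # A, C1' distance from the helix axis

# Rigid sugar/backbone fragment, C1' at the origin, glycosidic bond along +x.
_SUGAR = [
    ("P", (-3.50, 4.30, 0.60)),
    ("OP1", (-4.80, 4.10, 1.20)),
    ("OP2", (-3.40, 5.50, 1.40)),
    ("O5'", (-2.60, 3.10, 1.00)),
    ("C5'", (-2.90, 1.85, 0.40)),
    ("C4'", (-1.97, 0.78, 0.83)),
    ("O4'", (-0.471, 1.329, 0.0)),
    ("C3'", (-2.16, -0.63, 0.28)),
    ("O3'", (-3.11, -1.58, 0.73)),
    ("C2'", (-0.75, -1.08, 0.62)),
    ("O2'", (-0.42, -2.41, 0.35)),
    ("C1'", (0.0, 0.0, 0.0)),
    ("H1'", (-0.36, -0.59, 0.83)),
]

_GLYCO_N = 1.47  # C1'-N bond length


def _hexagon(center_x: float, radius: float, names_at_deg):
    out = []
    for name, deg in names_at_deg:
        th = np.radians(deg)
        out.append((name, (center_x + radius * np.cos(th), radius * np.sin(th), 0.0)))
    return out


def _pyrimidine_base(kind: str):
    """Planar pyrimidine ring, N1 at the glycosidic attachment point."""
    c = _GLYCO_N + 1.38
    ring = _hexagon(
        c, 1.38,
        [("N1", 180), ("C2", 240), ("N3", 300), ("C4", 0), ("C5", 60), ("C6", 120)],
    )
    exo = _hexagon(c, 1.38 + 1.28, [("O2", 240)])
    if kind == "C":
        n4 = _hexagon(c, 1.38 + 1.33, [("N4", 0)])
        x4, y4, _ = n4[0][1]
        exo += n4 + [
            ("H41", (x4 + 0.87, y4 + 0.50, 0.0)),
            ("H42", (x4 + 0.87, y4 - 0.50, 0.0)),
        ]
    else:  # U
        exo += _hexagon(c, 1.38 + 1.23, [("O4", 0)])
    return ring + exo


def _purine_base(kind: str):
    """Planar fused purine rings, N9 at the glycosidic attachment point."""
    c5 = _GLYCO_N + 1.17
    penta = _hexagon(
        c5, 1.17,
        [("N9", 180), ("C8", 108), ("N7", 36), ("C5", -36), ("C4", -108)],
    )
    coords = dict((n, np.array(p)) for n, p in penta)
    n3 = coords["C4"] + np.array([0.80, -1.10, 0.0])
    c2 = n3 + np.array([1.30, -0.30, 0.0])
    n1 = c2 + np.array([1.25, 0.65, 0.0])
    c6 = n1 + np.array([0.10, 1.38, 0.0])
    hexa = [("N3", n3), ("C2", c2), ("N1", n1), ("C6", c6)]
    if kind == "G":
        hexa += [("O6", c6 + np.array([0.90, 0.90, 0.0])),
                 ("N2", c2 + np.array([0.95, -0.95, 0.0]))]
    else:  # A
        hexa += [("N6", c6 + np.array([0.90, 0.90, 0.0]))]
    return penta + [(n, tuple(p)) for n, p in hexa]


_BASES = {
    "A": _purine_base("A"),
    "G": _purine_base("G"),
    "C": _pyrimidine_base("C"),
    "U": _pyrimidine_base("U"),
}
_SUGAR_NAMES = {name for name, _ in _SUGAR}


def _rot_x(deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_z(deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _element(name: str) -> str:
    return name.lstrip("0123456789")[:1].upper()


def _residue_template(letter: str, chi_target: float):
    """Atom names and local coordinates of one nucleotide at an exact chi."""
    if letter not in _BASES:
        raise ValueError(f"invalid nucleotide letter {letter!r}")
    names = [n for n, _ in _SUGAR] + [n for n, _ in _BASES[letter]]
    coords = np.array(
        [p for _, p in _SUGAR] + [p for _, p in _BASES[letter]], dtype=float
    )
    lookup = {n: coords[i] for i, n in enumerate(names)}
    quad = CHI_ATOMS["purine" if letter in "AG" else "pyrimidine"]
    chi0 = dihedral(*(lookup[a] for a in quad))
    # base atoms rotate rigidly about the glycosidic (x) axis; the rotation
    # adds (+-) linearly to chi, so one correction lands exactly on target
    n_sugar = len(_SUGAR)
    for delta in (chi_target - chi0, chi0 - chi_target):
        rotated = coords.copy()
        rotated[n_sugar:] = coords[n_sugar:] @ _rot_x(delta).T
        look = {n: rotated[i] for i, n in enumerate(names)}
        achieved = dihedral(*(look[a] for a in quad))
        if abs((achieved - chi_target + 180.0) % 360.0 - 180.0) < 1e-9:
            return names, rotated
    raise AssertionError("chi rotation failed to reach target")


def _build_strand(sequence: str, chi: np.ndarray, rise: float, twist: float):
    """One strand along +z; returns (atom names per residue, coordinates)."""
    L = len(sequence)
    center = (L - 1) / 2.0
    all_names, all_coords = [], []
    for k, letter in enumerate(sequence):
        names, local = _residue_template(letter, chi[k])
        placed = (local + np.array([HELIX_RADIUS, 0.0, 0.0])) @ _rot_z(k * twist).T
        placed = placed + np.array([0.0, 0.0, (k - center) * rise])
        all_names.append(names)
        all_coords.append(placed)
    return all_names, all_coords


def build_duplex(
    sequence,
    chi=None,
    rise: float = HELICAL_RISE,
    twist: float = HELICAL_TWIST,
    displacements: dict[int, np.ndarray] | None = None,
    symmetry: bool | None = None,
) -> tuple[Topology, np.ndarray]:
    """Build an idealized antiparallel duplex with exact chi targets.

    Parameters
    ----------
    sequence : str or (str, str)
        One strand (duplexed with an identical copy, the self-complementary
        case) or two explicit strands of equal length.
    chi : dict | array | None
        Per-residue chi target in degrees, keyed by global residue index
        (strand 1: 0..L-1, strand 2: L..2L-1).  Default: anti (-160 deg)
        everywhere.
    displacements : dict[int, 3-vector] | None
        Rigid per-residue translations applied after placement (chi is
        unaffected); used to make state templates geometrically distinct
        and to build dispersed noise frames.
    symmetry : bool | None
        Attach the strand-swap permutation; default: yes when the two
        strands have the same sequence.

    Returns (topology, coordinates) with coordinates shaped (n_atoms, 3).
    """
    if isinstance(sequence, str):
        strands = (sequence, sequence)
    else:
        strands = tuple(sequence)
    s1, s2 = strands
    if len(s1) != len(s2):
        raise ValueError("strands must have equal length")
    L = len(s1)
    n_res = 2 * L
    if chi is None:
        chi_arr = np.full(n_res, CHI_ANTI)
    elif isinstance(chi, dict):
        chi_arr = np.full(n_res, CHI_ANTI)
        for k, v in chi.items():
            chi_arr[k] = v
    else:
        chi_arr = np.asarray(chi, dtype=float)

    names1, coords1 = _build_strand(s1, chi_arr[:L], rise, twist)
    names2, coords2 = _build_strand(s2, chi_arr[L:], rise, twist)
    # strand 2 is the C2 image of a standalone strand: 180 deg about x
    R = _rot_x(180.0)
    coords2 = [c @ R.T for c in coords2]

    atoms: list[Atom] = []
    residues: list[Residue] = []
    coord_rows: list[np.ndarray] = []
    for chain_id, seq, names, coords in (
        ("A", s1, names1, coords1),
        ("B", s2, names2, coords2),
    ):
        for k, letter in enumerate(seq):
            start = len(atoms)
            ridx = len(residues)
            for name in names[k]:
                atoms.append(Atom(name, _element(name), ridx, letter, chain_id))
            residues.append(
                Residue(chain_id, ridx, letter, start, len(atoms), resseq=k + 1)
            )
            coord_rows.append(coords[k])
    frame = np.vstack(coord_rows)

    if displacements:
        for ridx, vec in displacements.items():
            res = residues[ridx]
            frame[res.start : res.stop] += np.asarray(vec, dtype=float)

    topology = Topology(atoms, residues)
    if symmetry is None:
        symmetry = s1 == s2
    if symmetry:
        topology = set_symmetry(topology, {"A": "B"})
    return topology, frame


@dataclass
class StateTemplate:
    """A named conformational state: chi targets plus a rigid offset."""

    name: str
    chi: dict[int, float]  # global residue index -> chi target (deg)
    displacement: dict[int, tuple] = field(default_factory=dict)


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic duplex ensemble with known ground truth.

    Frames are drawn from ``templates`` either with exact per-template
    ``counts`` or multinomially from ``weights``; ``n_noise`` additional
    frames are dispersed singletons (independent large random translations
    of every loop residue).  Isotropic Gaussian noise of ``noise_sigma`` A
    is added to every coordinate.  Frame order is shuffled, or follows a
    Markov chain over templates when ``transition`` is given.  All draws
    come from one generator stream seeded with ``seed``.
    """

    sequence: str
    loop: tuple[tuple[int, ...], tuple[int, ...]]
    templates: list[StateTemplate]
    counts: dict[str, int] | None = None
    weights: dict[str, float] | None = None
    n_frames: int | None = None
    n_noise: int = 0
    noise_sigma: float = 0.15
    seed: int = 0
    transition: np.ndarray | None = None
    min_separation: float = 4.0
    noise_shift_range: tuple[float, float] = (6.0, 12.0)


def markov_labels(
    transition: np.ndarray, n: int, seed: int, states: list[str] | None = None
):
    """Sample a state-label sequence from a Markov chain.

    The first label is drawn from the stationary distribution; the matrix
    must be row-stochastic.  Returns an array of state names (or integer
    indices when ``states`` is None).
    """
    T = np.asarray(transition, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    # stationary distribution: left eigenvector of eigenvalue 1
    w, v = np.linalg.eig(T.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    k = T.shape[0]
    seq = np.empty(n, dtype=int)
    seq[0] = rng.choice(k, p=pi)
    for i in range(1, n):
        seq[i] = rng.choice(k, p=T[seq[i - 1]])
    if states is not None:
        return np.asarray(states, dtype=object)[seq]
    return seq


def sample_ensemble(spec: EnsembleSpec) -> tuple[Trajectory, np.ndarray]:
    """Generate a trajectory and its ground-truth per-frame template labels.

    Noise frames are labelled "noise".  Template structures are verified to
    be at least ``spec.min_separation`` A apart in symmetry-minimised RMSD
    over the loop heavy atoms, so clustering at a smaller cutoff provably
    recovers the construction partition.
    """
    if spec.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(spec.seed)

    topology = None
    template_coords: dict[str, np.ndarray] = {}
    for tmpl in spec.templates:
        topo, frame = build_duplex(
            spec.sequence, chi=tmpl.chi, displacements=tmpl.displacement
        )
        topology = topology or topo
        template_coords[tmpl.name] = frame

    loop_residues = list(spec.loop[0]) + list(spec.loop[1])
    loop_heavy = select_atoms(topology, residues=loop_residues, heavy=True)
    names = [t.name for t in spec.templates]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d, _ = symmetry_min_rmsd(
                template_coords[names[i]], template_coords[names[j]],
                topology, loop_heavy,
            )
            if d < spec.min_separation:
                raise ValueError(
                    f"templates {names[i]!r} and {names[j]!r} are only "
                    f"{d:.2f} A apart (< {spec.min_separation} A); adjust "
                    "their displacements"
                )

    # --- per-frame labels (draw order: labels, noise shifts, coordinate noise)
    if spec.transition is not None:
        if spec.n_frames is None:
            raise ValueError("markov ordering requires n_frames")
        labels = markov_labels(
            spec.transition, spec.n_frames, rng.integers(2**31), states=names
        )
    elif spec.counts is not None:
        labels = np.concatenate(
            [np.repeat(name, cnt) for name, cnt in spec.counts.items()]
            + ([np.repeat("noise", spec.n_noise)] if spec.n_noise else [])
        ).astype(object)
        rng.shuffle(labels)
    elif spec.weights is not None:
        if spec.n_frames is None:
            raise ValueError("weight mode requires n_frames")
        w = np.array([spec.weights[n] for n in names], dtype=float)
        w = w / w.sum()
        labels = np.asarray(names, dtype=object)[
            rng.choice(len(names), size=spec.n_frames, p=w)
        ]
    else:
        raise ValueError("spec needs counts, weights or a transition matrix")

    frames = np.empty((len(labels), topology.n_atoms, 3))
    base = template_coords[names[0]]
    lo, hi = spec.noise_shift_range
    for f, lab in enumerate(labels):
        if lab == "noise":
            coords = base.copy()
            for r in loop_residues:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                shift = rng.uniform(lo, hi) * direction
                res = topology.residues[r]
                coords[res.start : res.stop] += shift
            frames[f] = coords
        else:
            frames[f] = template_coords[lab]
    if spec.noise_sigma > 0:
        frames += rng.normal(scale=spec.noise_sigma, size=frames.shape)
    return Trajectory(frames, topology), labels


# ---------------------------------------------------------------------------
# Ready-made constructions


GG_SEQUENCE = "UCUGGGGCCAGA"  # self-complementary; central 2x2 GG/GG loop
GG_LOOP = ((5, 6), (17, 18))  # loop residues, strand 1 / strand 2 (global ids)

# The four observed 2x2 GG/GG loop states, letters 5'->3' per strand.  Each
# template carries a distinct rigid offset of the strand-1 loop residues:
# with a perfectly C2-symmetric build, sa/as and as/sa would be exact
# strand-swap images of each other (symmetry-minimised RMSD 0) and clustering
# would merge them, unlike real ensembles where the states are geometrically
# distinct.  The offsets are chi-preserving rigid translations.
GG_STATES = [
    ("sa/as", ("s", "a", "a", "s"), {}),
    ("as/as", ("a", "s", "a", "s"), {5: (14.0, 0.0, 7.0), 6: (14.0, 0.0, 7.0)}),
    ("aa/aa", ("a", "a", "a", "a"), {5: (0.0, 14.0, -7.0), 6: (0.0, 14.0, -7.0)}),
    ("as/sa", ("a", "s", "s", "a"),
     {5: (-14.0, -18.0, 10.0), 6: (-14.0, -18.0, 10.0)}),
]


def gg_loop_spec(
    counts: dict[str, int],
    n_noise: int = 0,
    noise_sigma: float = 0.15,
    seed: int = 0,
    chi_syn: float = CHI_SYN,
    chi_anti: float = CHI_ANTI,
    **kwargs,
) -> EnsembleSpec:
    """EnsembleSpec for the 2x2 GG/GG duplex with the four observed states.

    ``counts`` keys are state names as strand1/strand2 letter strings in
    build order (e.g. "sa/as"); note report labels are canonicalised over
    the strand swap, so "sa/as" is reported as "as/sa".
    """
    by_name = {name: (letters, disp) for name, letters, disp in GG_STATES}
    loop_ids = list(GG_LOOP[0]) + list(GG_LOOP[1])
    templates = []
    for name in counts:
        if name == "noise":
            continue
        letters, disp = by_name[name]
        chi = {
            r: (chi_syn if s == "s" else chi_anti)
            for r, s in zip(loop_ids, letters)
        }
        templates.append(StateTemplate(name, chi, dict(disp)))
    clean = {k: v for k, v in counts.items() if k != "noise"}
    return EnsembleSpec(
        sequence=GG_SEQUENCE,
        loop=GG_LOOP,
        templates=templates,
        counts=clean,
        n_noise=n_noise + counts.get("noise", 0),
        noise_sigma=noise_sigma,
        seed=seed,
        **kwargs,
    )


GG_SURVEY_SEQUENCE = "ACGCA"  # central 1x1 G/G mismatch when self-paired
GG_SURVEY_LOOP = ((2,), (7,))


def gg_survey_trajectory(
    counts: dict[str, int],
    seed: int = 0,
    chi_syn: float = CHI_SYN,
    chi_anti: float = CHI_ANTI,
) -> Trajectory:
    """A collection of 1x1 G/G loop structures with prescribed states.

    ``counts`` maps labels like "a/s" (strand1 letter / strand2 letter) to
    structure counts; the returned Trajectory holds one frame per structure
    in shuffled order.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate(
        [np.repeat(name, cnt) for name, cnt in counts.items()]
    ).astype(object)
    rng.shuffle(labels)
    topology = None
    frames = []
    cache: dict[str, np.ndarray] = {}
    for lab in labels:
        if lab not in cache:
            l1, l2 = lab.split("/")
            chi = {
                GG_SURVEY_LOOP[0][0]: chi_syn if l1 == "s" else chi_anti,
                GG_SURVEY_LOOP[1][0]: chi_syn if l2 == "s" else chi_anti,
            }
            topo, frame = build_duplex(GG_SURVEY_SEQUENCE, chi=chi)
            topology = topology or topo
            cache[lab] = frame
        frames.append(cache[lab])
    return Trajectory(np.stack(frames), topology)
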