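"""Energy terms and their geometry kernels.

Every term maps oracle output (or the bare sequences) for a State to a
scalar; the design objective is the weighted sum of such terms.  Terms
follow an N-body convention borrowed from molecular simulation:
zero-body terms see the whole State (pTM, chemical potential), one-body
terms act on a single residue group (pLDDT, hydrophobic fraction,
surface area, secondary structure, template match), two-body terms on a
pair of groups (PAE, separation), and the ring-symmetry term on an
arbitrary list of groups.

Geometry kernels used by the structural terms are exposed as plain
functions operating on numpy arrays: Shrake–Rupley solvent-accessible
surface area, least-squares rigid superposition, and Cα-based
secondary-structure assignment (P-SEA, via biotite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from .core import EnergyTerm, EvalContext, MaterializedGroup, State
from .errors import ConfigurationError
from .oracles import BACKBONE_ATOMS, EmbedOutput, FoldOutput, PAE_MAX

#: Strongly hydrophobic residues (the default counting set).
HYDROPHOBIC_STRICT = frozenset("VILFMW")
#: Mildly hydrophobic residues, included only on request.
HYDROPHOBIC_MILD = frozenset("YCAG")

#: Heavy-atom van der Waals radii in Angstrom.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SASA_POINTS = 1000
#: Free solvent-accessible area of a probe-expanded sulfur atom.
SASA_MAX_DEFAULT = 4.0 * np.pi * (VDW_RADII["S"] + DEFAULT_PROBE_RADIUS) ** 2

SS_LABELS = ("helix", "sheet", "coil")


# ----------------------------------------------------------------------
# sequence terms
# ----------------------------------------------------------------------


def hydrophobic_energy(sequence: str, sasa_weights: Sequence[float] | None = None,
                       include_mild: bool = False) -> float:
    """Fraction of hydrophobic residues in a group.

    With ``sasa_weights`` (per-residue mean normalized SASA in [0, 1]),
    each hydrophobic residue contributes its weight instead of 1, so
    buried hydrophobes cost little and exposed ones the full amount.
    """
    if len(sequence) == 0:
        raise ConfigurationError("hydrophobic energy needs a non-empty group")
    hydro = HYDROPHOBIC_STRICT | HYDROPHOBIC_MILD if include_mild else HYDROPHOBIC_STRICT
    if sasa_weights is None:
        weights = [1.0] * len(sequence)
    else:
        weights = list(sasa_weights)
        if len(weights) != len(sequence):
            raise ConfigurationError("one SASA weight per residue required")
    total = sum(w for aa, w in zip(sequence, weights) if aa in hydro)
    return total / len(sequence)


def chemical_potential_energy(mu: float, n_total: int, n_target: int,
                              p: float = 1.0) -> float:
    """mu * |N_total - N_target|**p — the grand-canonical length anchor."""
    if p <= 0:
        raise ConfigurationError("chemical potential exponent must be > 0")
    return mu * abs(n_total - n_target) ** p


# ----------------------------------------------------------------------
# folding-metric terms
# ----------------------------------------------------------------------


def ptm_energy(ptm: float) -> float:
    """-pTM: lower energy for globally confident predictions."""
    return -float(ptm)


def plddt_energy(plddt_values: Sequence[float]) -> float:
    """Negative mean per-residue pLDDT over a group."""
    values = np.asarray(plddt_values, dtype=float)
    if values.size == 0:
        raise ConfigurationError("pLDDT energy needs a non-empty group")
    return float(-values.mean())


def pae_energy(pae: np.ndarray, indices_1: Sequence[int],
               indices_2: Sequence[int] | None = None,
               pae_max: float = PAE_MAX) -> float:
    """Mean normalized predicted-alignment error between two groups.

    PAE matrices are asymmetric, so both directed blocks (G1→G2 and
    G2→G1) are averaged; in single-group mode all ordered pairs with
    distinct residues are used.
    """
    if pae_max <= 0:
        raise ConfigurationError("pae_max must be > 0")
    pae = np.asarray(pae, dtype=float)
    i1 = np.asarray(indices_1, dtype=int)
    if i1.size == 0:
        raise ConfigurationError("PAE energy needs non-empty groups")
    if indices_2 is None:
        sub = pae[np.ix_(i1, i1)]
        n = i1.size
        if n < 2:
            raise ConfigurationError("single-group PAE needs >= 2 residues")
        total = sub.sum() - np.trace(sub)
        return float(total / (n * (n - 1)) / pae_max)
    i2 = np.asarray(indices_2, dtype=int)
    if i2.size == 0:
        raise ConfigurationError("PAE energy needs non-empty groups")
    total = pae[np.ix_(i1, i2)].sum() + pae[np.ix_(i2, i1)].sum()
    return float(total / (2 * i1.size * i2.size) / pae_max)


# ----------------------------------------------------------------------
# geometry kernels
# ----------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate/translate a coordinate set into a deterministic frame
    (principal axes, signs fixed by the third moment) so that point-
    lattice sampling is exactly invariant under rigid motions of the
    input.  Degenerate (highly symmetric) clouds may still flip axes;
    those are measure-zero for molecular structures."""
    centered = coords - coords.mean(axis=0)
    if len(centered) < 2:
        return centered
    cov = centered.T @ centered
    _, axes = np.linalg.eigh(cov)
    rotated = centered @ axes
    skew = (rotated ** 3).sum(axis=0)
    signs = np.where(skew < 0, -1.0, 1.0)
    rotated = rotated * signs
    if np.linalg.det(axes * signs) < 0:  # keep the frame right-handed
        rotated[:, 0] *= -1
    return rotated


def shrake_rupley_sasa(coords: np.ndarray, elements: Sequence[str],
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_points: int = DEFAULT_SASA_POINTS,
                       canonicalize: bool = True) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), rolling-probe style.

    Each atom's sphere is expanded by the probe radius and sampled with
    a quasi-uniform point lattice; points strictly inside any other
    expanded sphere are buried.  Hydrogens are not modelled — the radii
    table covers heavy atoms only.  ``canonicalize`` first moves the
    structure into a deterministic principal-axes frame, making the
    result exactly invariant under rigid motions of the input (the
    lattice itself is orientation-dependent).
    """
    coords = np.asarray(coords, dtype=float)
    if canonicalize and len(coords):
        coords = _canonical_frame(coords)
    if n_points < 1:
        raise ConfigurationError("n_points must be >= 1")
    if probe_radius < 0:
        raise ConfigurationError("probe_radius must be >= 0")
    try:
        radii = np.array([VDW_RADII[e] for e in elements]) + probe_radius
    except KeyError as exc:
        raise ConfigurationError(f"unknown element {exc.args[0]!r}") from None
    if coords.shape != (len(radii), 3):
        raise ConfigurationError("coords must be (n_atoms, 3) matching elements")
    unit = _sphere_points(n_points)
    n_atoms = len(radii)
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * unit
        # neighbours whose expanded sphere can reach atom i's surface
        d = np.linalg.norm(coords - coords[i], axis=1)
        near = (d < radii[i] + radii) & (np.arange(n_atoms) != i)
        accessible = np.ones(n_points, dtype=bool)
        for j in np.nonzero(near)[0]:
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas


def optimal_superposition(mobile: np.ndarray, reference: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of matched atom sets.

    Returns ``(rotation, translation, rmsd)`` with
    ``reference ≈ rotation @ mobile + translation``; the rotation is
    proper (reflections are corrected), so the RMSD is the minimum over
    rigid motions.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ConfigurationError(
            f"atom count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ConfigurationError("superposition needs >= 3 matched 3-D atoms")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_mean, mobile - mob_mean)
    matrix = rot.as_matrix()
    translation = ref_mean - matrix @ mob_mean
    # rmsd from the residuals directly: better conditioned near zero than
    # the solver's residual sum of squares
    residual = mobile @ matrix.T + translation - reference
    rmsd = float(np.sqrt(np.mean(np.sum(residual ** 2, axis=1))))
    return matrix, translation, rmsd


def assign_secondary_structure(ca_coords: np.ndarray) -> list[str]:
    """Per-residue secondary structure from Cα geometry (P-SEA).

    ``ca_coords`` is (n, 3); rows with any non-finite entry mark a
    missing Cα and are labelled coil with a warning.  Residues matching
    neither the helix nor the sheet criteria are coil; stretches too
    short for the sliding windows (fewer than 5 residues) are coil.
    """
    ca_coords = np.asarray(ca_coords, dtype=float)
    n = ca_coords.shape[0]
    labels = ["coil"] * n
    valid = np.all(np.isfinite(ca_coords), axis=1)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} residue(s) without Cα labelled coil",
            stacklevel=2,
        )
    translate = {"a": "helix", "b": "sheet", "c": "coil"}
    # annotate each contiguous run of present Cα atoms independently
    start = None
    for i in range(n + 1):
        if i < n and valid[i]:
            if start is None:
                start = i
            continue
        if start is not None:
            seg = ca_coords[start:i]
            if len(seg) >= 5:
                arr = struc.AtomArray(len(seg))
                arr.coord = seg.astype(np.float32)
                arr.chain_id[:] = "A"
                arr.res_id[:] = np.arange(1, len(seg) + 1)
                arr.res_name[:] = "ALA"
                arr.atom_name[:] = "CA"
                arr.element[:] = "C"
                for k, code in enumerate(struc.annotate_sse(arr)):
                    labels[start + k] = translate[str(code)]
            start = None
    return labels


def _centroid(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ConfigurationError("centroid of an empty atom set")
    return coords.mean(axis=0)


# ----------------------------------------------------------------------
# structural terms (functional forms)
# ----------------------------------------------------------------------


def surface_area_energy(sasa_values: Sequence[float],
                        sasa_max: float = SASA_MAX_DEFAULT) -> float:
    """Mean atom SASA normalized by a reference maximum area."""
    values = np.asarray(sasa_values, dtype=float)
    if values.size == 0:
        raise ConfigurationError("surface-area energy needs at least one atom")
    return float(values.mean() / sasa_max)


def separation_energy(coords_1: np.ndarray, coords_2: np.ndarray) -> float:
    """Distance (Å) between two groups' backbone centroids."""
    return float(np.linalg.norm(_centroid(coords_1) - _centroid(coords_2)))


def globular_energy(coords: np.ndarray) -> float:
    """Std of backbone-atom distances to the group centroid (Å).

    Zero for a perfect spherical shell; grows for elongated shapes —
    effectively a radius-of-gyration spread penalty.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ConfigurationError("globular energy needs >= 2 backbone atoms")
    d = np.linalg.norm(coords - _centroid(coords), axis=1)
    return float(np.std(d))


def template_match_energy(coords: np.ndarray, template_coords: np.ndarray,
                          mode: str = "rmsd") -> float:
    """Deviation of a group's structure from a fixed template.

    ``rmsd`` mode: mean squared atom deviation after optimal rigid
    superposition (zero iff the group is a rigid transform of the
    template).  ``distogram`` mode: mean squared difference of all
    pairwise atom distances — superposition-free and equally zero on
    rigid transforms.
    """
    coords = np.asarray(coords, dtype=float)
    template_coords = np.asarray(template_coords, dtype=float)
    if coords.shape != template_coords.shape:
        raise ConfigurationError(
            f"template/group atom mismatch: {coords.shape} vs {template_coords.shape}")
    if mode == "rmsd":
        _, _, rmsd = optimal_superposition(coords, template_coords)
        return float(rmsd ** 2)
    if mode == "distogram":
        n = coords.shape[0]
        if n < 2:
            raise ConfigurationError("distogram mode needs >= 2 atoms")
        iu = np.triu_indices(n, k=1)
        d = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
        dt = np.linalg.norm(template_coords[iu[0]] - template_coords[iu[1]], axis=1)
        return float(np.mean((d - dt) ** 2))
    raise ConfigurationError(f"unknown template mode {mode!r}")


def secondary_structure_energy(labels: Sequence[str], target: str) -> float:
    """Fraction of residues whose assigned structure misses the target."""
    if target not in SS_LABELS:
        raise ConfigurationError(f"target must be one of {SS_LABELS}")
    labels = list(labels)
    if not labels:
        raise ConfigurationError("secondary-structure energy needs a non-empty group")
    return sum(1 for lab in labels if lab != target) / len(labels)


def ring_symmetry_energy(group_coords: Sequence[np.ndarray],
                         mode: str = "all_pairs") -> float:
    """Spread (std, Å) of centroid–centroid distances across N groups.

    ``all_pairs`` considers every unordered pair of group centroids;
    ``neighbors`` only consecutive groups in input order, cyclically
    (first and last are neighbours).  Zero for perfectly N-fold
    symmetric arrangements.
    """
    if len(group_coords) < 3:
        raise ConfigurationError("ring symmetry needs >= 3 residue groups")
    centroids = np.stack([_centroid(c) for c in group_coords])
    n = len(centroids)
    if mode == "all_pairs":
        iu = np.triu_indices(n, k=1)
        d = np.linalg.norm(centroids[iu[0]] - centroids[iu[1]], axis=1)
    elif mode == "neighbors":
        nxt = np.roll(np.arange(n), -1)
        d = np.linalg.norm(centroids - centroids[nxt], axis=1)
    else:
        raise ConfigurationError(f"unknown ring-symmetry mode {mode!r}")
    return float(np.std(d))


def embeddings_similarity_energy(vectors: np.ndarray,
                                 reference_vectors: np.ndarray) -> float:
    """1 − mean cosine similarity between current and reference embeddings.

    Vectors are normalized first; the minimum 0 is attained exactly
    when every embedding equals its reference (up to scale), and the
    maximum 2 when all pairs are antiparallel.
    """
    v = np.asarray(vectors, dtype=float)
    r = np.asarray(reference_vectors, dtype=float)
    if v.shape != r.shape:
        raise ConfigurationError(
            f"embedding shape mismatch: {v.shape} vs {r.shape}")
    if v.size == 0:
        raise ConfigurationError("embedding energy needs a non-empty group")
    nv = np.linalg.norm(v, axis=1)
    nr = np.linalg.norm(r, axis=1)
    if np.any(nv == 0) or np.any(nr == 0):
        raise ConfigurationError("zero-norm embedding vector")
    cos = np.sum((v / nv[:, None]) * (r / nr[:, None]), axis=1)
    return float(1.0 - cos.mean())


# ----------------------------------------------------------------------
# template container
# ----------------------------------------------------------------------


@dataclass
class TemplateStructure:
    """Reference coordinates keyed by (residue order in group, atom name).

    ``residues`` is a list, one entry per group residue in group order,
    each a dict mapping atom name to its 3-D position.
    """

    residues: list[dict[str, np.ndarray]]

    @classmethod
    def from_file(cls, path: str, atom_set: str = "all_heavy") -> "TemplateStructure":
        """Load from mmCIF or PDB; one entry per residue in file order."""
        import biotite.structure.io as strucio

        arr = strucio.load_structure(str(path))
        if arr.array_length() == 0:
            raise ConfigurationError(f"no atoms in template file {path!r}")
        if atom_set == "backbone":
            arr = arr[np.isin(arr.atom_name, BACKBONE_ATOMS)]
        elif atom_set == "all_heavy":
            arr = arr[arr.element != "H"]
        else:
            raise ConfigurationError(f"unknown atom_set {atom_set!r}")
        residues: list[dict[str, np.ndarray]] = []
        starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
        for lo, hi in zip(starts[:-1], starts[1:]):
            residues.append({
                str(arr.atom_name[i]): np.array(arr.coord[i], dtype=float)
                for i in range(lo, hi)
            })
        return cls(residues=residues)

    @classmethod
    def from_fold_output(cls, fold: FoldOutput, residue_indices: Sequence[int],
                         atom_set: str = "all_heavy") -> "TemplateStructure":
        residues = []
        for idx in residue_indices:
            mask = fold.atom_mask([idx], BACKBONE_ATOMS if atom_set == "backbone" else None)
            residues.append({
                str(name): np.array(xyz, dtype=float)
                for name, xyz in zip(fold.atom_names[mask], fold.coords[mask])
            })
        return cls(residues=residues)

    def matched_coords(self, fold: FoldOutput, abs_indices: Sequence[int],
                       atom_set: str) -> tuple[np.ndarray, np.ndarray]:
        """Pair up group atoms with template atoms, in group order.

        Raises listing any atom the template is missing.
        """
        if len(abs_indices) != len(self.residues):
            raise ConfigurationError(
                f"template covers {len(self.residues)} residues but the group "
                f"has {len(abs_indices)}")
        names_filter = BACKBONE_ATOMS if atom_set == "backbone" else None
        mobile, reference, missing = [], [], []
        for order, idx in enumerate(abs_indices):
            mask = fold.atom_mask([idx], names_filter)
            for name, xyz in zip(fold.atom_names[mask], fold.coords[mask]):
                tmpl = self.residues[order].get(str(name))
                if tmpl is None:
                    missing.append(f"residue {order}:{name}")
                else:
                    mobile.append(xyz)
                    reference.append(tmpl)
        if missing:
            raise ConfigurationError(
                "template is missing atoms: " + ", ".join(missing))
        return np.asarray(mobile, dtype=float), np.asarray(reference, dtype=float)


# ----------------------------------------------------------------------
# term classes (bindable into States)
# ----------------------------------------------------------------------


def _abs_indices(state: State, group: MaterializedGroup) -> list[int]:
    """Chain-local group indices → State-concatenated residue indices."""
    off = state.residue_offset(group.chain.chain_id)
    return [off + i for i in group.indices]


def _require_groups(ctx: EvalContext, low: int, high: int | None, name: str) -> None:
    n = len(ctx.groups)
    if n < low or (high is not None and n > high):
        raise ConfigurationError(
            f"{name} expects between {low} and {high if high is not None else 'N'} "
            f"groups, got {n}")
    for g in ctx.groups:
        if len(g) == 0:
            raise ConfigurationError(f"{name}: a bound residue group became empty")


def _residue_sasa_weights(fold: FoldOutput, abs_indices: Sequence[int],
                          probe_radius: float, n_points: int) -> np.ndarray:
    """Per-residue mean normalized SASA over the residue's heavy atoms."""
    areas = shrake_rupley_sasa(fold.coords, fold.elements, probe_radius, n_points)
    radii = np.array([VDW_RADII[e] for e in fold.elements]) + probe_radius
    free = 4.0 * np.pi * radii ** 2
    norm = areas / free
    out = np.empty(len(abs_indices))
    for k, idx in enumerate(abs_indices):
        mask = fold.atom_residue_index == idx
        out[k] = norm[mask].mean() if mask.any() else 0.0
    return out


class HydrophobicEnergy(EnergyTerm):
    """Fraction of hydrophobic residues in a group (Å-free, sequence-only),
    optionally SASA-scaled to target *exposed* hydrophobes only."""

    name = "HydrophobicEnergy"
    n_groups = 1

    def __init__(self, include_mild: bool = False, sasa_scaled: bool = False,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = DEFAULT_SASA_POINTS):
        self.include_mild = include_mild
        self.sasa_scaled = sasa_scaled
        self.probe_radius = probe_radius
        self.n_points = n_points
        self.requires = "fold" if sasa_scaled else None

    def evaluate(self, ctx: EvalContext) -> float:
        _require_groups(ctx, 1, 1, self.name)
        group = ctx.groups[0]
        weights = None
        if self.sasa_scaled:
            weights = _residue_sasa_weights(
                ctx.oracle_output, _abs_indices(ctx.state, group),
                self.probe_radius, self.n_points)
        return hydrophobic_energy(group.sequence, weights, self.include_mild)


class ChemicalPotentialEnergy(EnergyTerm):
    """Anchors the System's total residue count near a target length."""

    name = "ChemicalPotentialEnergy"
    requires = None
    n_groups = 0

    def __init__(self, mu: float, n_target: int, p: float = 1.0):
        self.mu = float(mu)
        self.n_target = int(n_target)
        self.p = float(p)
        if self.p <= 0:
            raise ConfigurationError("chemical potential exponent must be > 0")

    def evaluate(self, ctx: EvalContext) -> float:
        return chemical_potential_energy(
            self.mu, ctx.system.total_residues, self.n_target, self.p)


class PTMEnergy(EnergyTerm):
    """Global fold confidence: energy is −pTM."""

    name = "PTMEnergy"
    requires = "fold"
    n_groups = 0

    def evaluate(self, ctx: EvalContext) -> float:
        return ptm_energy(ctx.oracle_output.ptm)


class PLDDTEnergy(EnergyTerm):
    """Local confidence: negative mean pLDDT over one residue group."""

    name = "PLDDTEnergy"
    requires = "fold"
    n_groups = 1

    def evaluate(self, ctx: EvalContext) -> float:
        _require_groups(ctx, 1, 1, self.name)
        idx = _abs_indices(ctx.state, ctx.groups[0])
        return plddt_energy(ctx.oracle_output.plddt[idx])


class OverallPLDDTEnergy(EnergyTerm):
    """Zero-body variant of PLDDTEnergy over every residue in the State."""

    name = "OverallPLDDTEnergy"
    requires = "fold"
    n_groups = 0

    def evaluate(self, ctx: EvalContext) -> float:
        return plddt_energy(ctx.oracle_output.plddt)


class PAEEnergy(EnergyTerm):
    """Mean normalized PAE between two groups (or within one).

    The two-group form is the interface-PAE surrogate used for binder
    design; a negative binding weight turns it into an avoidance term.
    """

    name = "PAEEnergy"
    requires = "fold"
    n_groups = None

    def __init__(self, pae_max: float = PAE_MAX):
        self.pae_max = float(pae_max)

    def evaluate(self, ctx: EvalContext) -> float:
        _require_groups(ctx, 1, 2, self.name)
        idx1 = _abs_indices(ctx.state, ctx.groups[0])
        idx2 = (_abs_indices(ctx.state, ctx.groups[1])
                if len(ctx.groups) == 2 else None)
        return pae_energy(ctx.oracle_output.pae, idx1, idx2, self.pae_max)


class SurfaceAreaEnergy(EnergyTerm):
    """Mean normalized SASA of a group's atoms (0 buried → 1 exposed).

    The group's atoms are scored inside the full State structure, so
    burial by other chains counts.
    """

    name = "SurfaceAreaEnergy"
    requires = "fold"
    n_groups = None  # 0 (whole State) or 1 group

    def __init__(self, sasa_max: float = SASA_MAX_DEFAULT,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = DEFAULT_SASA_POINTS):
        self.sasa_max = float(sasa_max)
        self.probe_radius = float(probe_radius)
        self.n_points = int(n_points)

    def evaluate(self, ctx: EvalContext) -> float:
        fold: FoldOutput = ctx.oracle_output
        areas = shrake_rupley_sasa(fold.coords, fold.elements,
                                   self.probe_radius, self.n_points)
        if len(ctx.groups) == 0:
            selected = areas
        else:
            _require_groups(ctx, 1, 1, self.name)
            mask = fold.atom_mask(_abs_indices(ctx.state, ctx.groups[0]))
            selected = areas[mask]
        return surface_area_energy(selected, self.sasa_max)


class SeparationEnergy(EnergyTerm):
    """Distance between two groups' backbone centroids (Å)."""

    name = "SeparationEnergy"
    requires = "fold"
    n_groups = 2

    def evaluate(self, ctx: EvalContext) -> float:
        _require_groups(ctx, 2, 2, self.name)
        fold: FoldOutput = ctx.oracle_output
        c1 = fold.backbone_coords(_abs_indices(ctx.state, ctx.groups[0]))
        c2 = fold.backbone_coords(_abs_indices(ctx.state, ctx.groups[1]))
        if c1.size == 0 or c2.size == 0:
            raise ConfigurationError("separation energy: missing backbone atoms")
        return separation_energy(c1, c2)


class GlobularEnergy(EnergyTerm):
    """Spread of backbone distances to the group centroid (Å)."""

    name = "GlobularEnergy"
    requires = "fold"
    n_groups = None  # 0 (whole State) or 1 group

    def evaluate(self, ctx: EvalContext) -> float:
        fold: FoldOutput = ctx.oracle_output
        if len(ctx.groups) == 0:
            coords = fold.coords[np.isin(fold.atom_names, BACKBONE_ATOMS)]
        else:
            _require_groups(ctx, 1, 1, self.name)
            coords = fold.backbone_coords(_abs_indices(ctx.state, ctx.groups[0]))
        return globular_energy(coords)


class TemplateMatchEnergy(EnergyTerm):
    """Deviation of a group from a fixed structural template.

    Non-inheritable: an inserted residue has no template counterpart,
    so membership would be ill-defined.
    """

    name = "TemplateMatchEnergy"
    requires = "fold"
    inheritable = False
    n_groups = 1

    def __init__(self, template: TemplateStructure, mode: str = "rmsd",
                 atom_set: str = "all_heavy"):
        if mode not in ("rmsd", "distogram"):
            raise ConfigurationError(f"unknown template mode {mode!r}")
        if atom_set not in ("all_heavy", "backbone"):
            raise ConfigurationError(f"unknown atom_set {atom_set!r}")
        self.template = template
        self.mode = mode
        self.atom_set = atom_set

    def evaluate(self, ctx: EvalContext) -> float:
        _require_groups(ctx, 1, 1, self.name)
        mobile, reference = self.template.matched_coords(
            ctx.oracle_output, _abs_indices(ctx.state, ctx.groups[0]), self.atom_set)
        return template_match_energy(mobile, reference, self.mode)


class SecondaryStructureEnergy(EnergyTerm):
    """Fraction of group residues missing a target secondary structure.

    Assignment runs over the group's whole chain (P-SEA needs the
    flanking geometry) and the group rows are then extracted.
    """

    name = "SecondaryStructureEnergy"
    requires = "fold"
    n_groups = 1

    def __init__(self, target: str):
        if target not in SS_LABELS:
            raise ConfigurationError(f"target must be one of {SS_LABELS}")
        self.target = target

    def evaluate(self, ctx: EvalContext) -> float:
        _require_groups(ctx, 1, 1, self.name)
        group = ctx.groups[0]
        fold: FoldOutput = ctx.oracle_output
        chain = group.chain
        off = ctx.state.residue_offset(chain.chain_id)
        chain_abs = list(range(off, off + len(chain)))
        ca = np.full((len(chain), 3), np.nan)
        mask = fold.atom_mask(chain_abs, ["CA"])
        for idx, xyz in zip(fold.atom_residue_index[mask], fold.coords[mask]):
            ca[int(idx) - off] = xyz
        labels = assign_secondary_structure(ca)
        group_labels = [labels[i] for i in group.indices]
        return secondary_structure_energy(group_labels, self.target)


class RingSymmetryEnergy(EnergyTerm):
    """N-fold symmetry pressure over ≥3 groups' backbone centroids."""

    name = "RingSymmetryEnergy"
    requires = "fold"
    n_groups = None

    def __init__(self, mode: str = "all_pairs"):
        if mode not in ("all_pairs", "neighbors"):
            raise ConfigurationError(f"unknown ring-symmetry mode {mode!r}")
        self.mode = mode

    def evaluate(self, ctx: EvalContext) -> float:
        _require_groups(ctx, 3, None, self.name)
        fold: FoldOutput = ctx.oracle_output
        coords = [fold.backbone_coords(_abs_indices(ctx.state, g))
                  for g in ctx.groups]
        return ring_symmetry_energy(coords, self.mode)


class EmbeddingsSimilarityEnergy(EnergyTerm):
    """Cosine dissimilarity between current and reference embeddings.

    ``reference`` is an :class:`EmbedOutput` (or array) for either the
    whole State (rows selected by absolute residue position) or exactly
    the group (rows aligned positionally with the group order).
    """

    name = "EmbeddingsSimilarityEnergy"
    requires = "embed"
    n_groups = 1

    def __init__(self, reference: EmbedOutput | np.ndarray):
        self.reference = (reference.vectors if isinstance(reference, EmbedOutput)
                          else np.asarray(reference, dtype=float))

    def evaluate(self, ctx: EvalContext) -> float:
        _require_groups(ctx, 1, 1, self.name)
        embed: EmbedOutput = ctx.oracle_output
        idx = _abs_indices(ctx.state, ctx.groups[0])
        current = embed.vectors[idx]
        if self.reference.shape[0] == len(idx):
            ref = self.reference
        else:
            try:
                ref = self.reference[idx]
            except IndexError:
                raise ConfigurationError(
                    "reference embeddings cover neither the group nor the "
                    "State's residue range") from None
        return embeddings_similarity_energy(current, ref)


#: Registry used by the declarative config reader and the CLI.
TERM_REGISTRY: dict[str, type[EnergyTerm]] = {
    cls.name: cls
    for cls in (
        HydrophobicEnergy, ChemicalPotentialEnergy, PTMEnergy, PLDDTEnergy,
        OverallPLDDTEnergy, PAEEnergy, SurfaceAreaEnergy, SeparationEnergy,
        GlobularEnergy, TemplateMatchEnergy, SecondaryStructureEnergy,
        RingSymmetryEnergy, EmbeddingsSimilarityEnergy,
    )
}
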