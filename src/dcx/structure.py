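"""Residue-residue interaction detection and ensemble frequencies on PDB structures.

Maps pattern positions onto crystal structures, detects hydrogen bonds,
van der Waals contacts and CH-pi interactions from heavy-atom geometry, and
tabulates how often each interaction occurs across a structure ensemble,
optionally stratified by functional state (active/inactive).  Selected
positions are finally joined with a user-supplied region annotation into the
tether taxonomy: N-lobe tether (NLT), active-site tether (AST) and C-lobe
tether (CLT).

Hydrogen bonds are detected without explicit hydrogens: a donor/acceptor
heavy-atom table per residue type, a donor-acceptor distance cutoff, an
angle check against every covalent antecedent of the donor, and — when the
donor's two antecedents fix the idealized amide-H direction — a minimum
D-H...A angle.  See the criteria dataclasses for the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .contrast import ContrastResults


class StructureFormatError(ValueError):
    """Unparseable or empty structure file."""


# ---------------------------------------------------------------------------
# Data model

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Hydrogen-bond donor heavy atoms per residue type (backbone N is implicit,
#: except proline which has no amide H).
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "TRP": ("NE1",),
}
#: Acceptor heavy atoms per residue type (backbone O/OXT implicit).
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",), "CYS": ("SG",),
}

#: Aromatic ring atom sets for CH-pi detection.
AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
}

#: Bondi van der Waals radii (Angstrom) by element.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos)


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, Atom]

    def atom(self, name: str) -> Atom | None:
        return self.atoms.get(name)


@dataclass
class Chain:
    chain_id: str
    residues: dict[int, Residue]  # keyed by author residue number, ordered

    def sorted_numbers(self) -> list[int]:
        return sorted(self.residues)


@dataclass
class Structure:
    """One protein structure (first model, highest-occupancy altlocs, no HET)."""

    structure_id: str
    chains: dict[str, Chain]
    state_label: str = "unassigned"  # 'active' | 'inactive' | 'unassigned'

    def iter_residues(self) -> Iterable[tuple[str, Residue]]:
        for cid, chain in self.chains.items():
            for res in chain.residues.values():
                yield cid, res

    def residue(self, chain_id: str, number: int) -> Residue | None:
        chain = self.chains.get(chain_id)
        return chain.residues.get(number) if chain else None

    def has_residue_number(self, number: int) -> bool:
        return any(number in c.residues for c in self.chains.values())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A rigidly moved copy (x -> R x + t); used for invariance checks."""
        chains = {}
        for cid, chain in self.chains.items():
            residues = {}
            for num, res in chain.residues.items():
                atoms = {
                    a.name: Atom(
                        a.name,
                        a.element,
                        tuple(rotation @ np.asarray(a.pos) + translation),
                    )
                    for a in res.atoms.values()
                }
                residues[num] = Residue(num, res.name, atoms)
            chains[cid] = Chain(cid, residues)
        return Structure(self.structure_id, chains, self.state_label)


def read_structure(
    path: str | Path,
    structure_id: str | None = None,
    state_label: str = "unassigned",
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    First model only; per atom name the highest-occupancy altloc is kept;
    waters, ligands and other heteroatoms are dropped (only the 20 standard
    amino acids are retained), as are hydrogens.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"no models in {path}")
    model = st[0]
    chains: dict[str, Chain] = {}
    for ch in model:
        residues: dict[int, Residue] = {}
        for res in ch:
            if res.name not in STANDARD_RESIDUES:
                continue
            best: dict[str, tuple[float, str, Atom]] = {}
            for at in res:
                if at.element.name == "H" or at.name.startswith("H"):
                    continue
                key = at.name
                cand = (
                    float(at.occ),
                    at.altloc or "~",  # '~' sorts after letters: prefer lettered? no —
                    Atom(at.name, at.element.name, (at.pos.x, at.pos.y, at.pos.z)),
                )
                prev = best.get(key)
                # keep highest occupancy; ties -> earliest altloc letter
                if prev is None or cand[0] > prev[0] or (
                    cand[0] == prev[0] and cand[1] < prev[1]
                ):
                    best[key] = cand
            if best:
                residues[res.seqid.num] = Residue(
                    res.seqid.num, res.name, {k: v[2] for k, v in best.items()}
                )
        if residues:
            chains[ch.name] = Chain(ch.name, residues)
    if not chains:
        raise StructureFormatError(f"no amino-acid residues in {path}")
    return Structure(structure_id or path.stem, chains, state_label)


# ---------------------------------------------------------------------------
# Interactions


@dataclass(frozen=True)
class Partner:
    chain: str
    number: int
    resname: str
    atom: str  # atom name, or ring descriptor like 'ring(CG..CZ)'

    def key(self) -> tuple:
        return (self.chain, self.number, self.atom)


@dataclass(frozen=True)
class Interaction:
    kind: str  # 'hbond' | 'vdw' | 'chpi'
    partner_a: Partner
    partner_b: Partner
    distance: float
    angle: float | None
    structure_id: str

    def residue_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        a = (self.partner_a.chain, self.partner_a.number)
        b = (self.partner_b.chain, self.partner_b.number)
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class HBondCriteria:
    """Heavy-atom hydrogen-bond geometry.

    d_max: donor-acceptor distance cutoff.  antecedent_angle_min: minimum
    angle (deg) at the donor against each covalent antecedent.  h_angle_min:
    minimum idealized D-H...A angle when the donor has exactly two
    antecedents (planar amide-type donor).  min_separation: minimum residue
    separation on the same chain unless both atoms are side-chain.
    """

    d_max: float = 3.5
    antecedent_angle_min: float = 90.0
    h_angle_min: float = 120.0
    min_separation: int = 2


@dataclass(frozen=True)
class VdwCriteria:
    tolerance: float = 0.5
    min_distance: float = 2.0  # below this, treat as covalent/clash, not contact
    min_separation: int = 2


@dataclass(frozen=True)
class ChPiCriteria:
    d_max: float = 4.5
    elevation_min: float = 30.0  # degrees above the ring plane


def _angle(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    v1, v2 = p - q, r - q
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


_COVALENT_CUTOFF = {"S": 2.1}
_DEFAULT_COVALENT_CUTOFF = 1.8


def _antecedents(
    s: Structure, chain_id: str, res: Residue, atom: Atom
) -> list[np.ndarray]:
    """Heavy atoms covalently bonded to ``atom`` (same residue, plus the
    preceding residue's C for a backbone N)."""
    out = []
    cutoff = max(
        _COVALENT_CUTOFF.get(atom.element, _DEFAULT_COVALENT_CUTOFF),
        _COVALENT_CUTOFF.get("S", 0) if atom.element == "S" else 0,
    )
    for other in res.atoms.values():
        if other.name == atom.name:
            continue
        d = float(np.linalg.norm(other.xyz - atom.xyz))
        if d < cutoff:
            out.append(other.xyz)
    if atom.name == "N":
        prev = s.residue(chain_id, res.number - 1)
        if prev is not None:
            c = prev.atom("C")
            if c is not None and np.linalg.norm(c.xyz - atom.xyz) < 1.8:
                out.append(c.xyz)
    return out


def _donor_atoms(res: Residue) -> list[Atom]:
    out = []
    if res.name != "PRO" and (n := res.atom("N")) is not None:
        out.append(n)
    for name in SIDECHAIN_DONORS.get(res.name, ()):
        if (a := res.atom(name)) is not None:
            out.append(a)
    return out


def _acceptor_atoms(res: Residue) -> list[Atom]:
    out = [a for n in ("O", "OXT") if (a := res.atom(n)) is not None]
    for name in SIDECHAIN_ACCEPTORS.get(res.name, ()):
        if (a := res.atom(name)) is not None:
            out.append(a)
    return out


def _separation_ok(
    chain_a: str, res_a: Residue, atom_a: str,
    chain_b: str, res_b: Residue, atom_b: str,
    min_separation: int,
) -> bool:
    if chain_a != chain_b:
        return True
    if abs(res_a.number - res_b.number) >= min_separation:
        return True
    return atom_a not in BACKBONE_ATOMS and atom_b not in BACKBONE_ATOMS


def detect_hbonds(
    s: Structure, criteria: HBondCriteria = HBondCriteria()
) -> list[Interaction]:
    """Donor-acceptor hydrogen bonds from heavy-atom geometry.

    A candidate passes when the donor-acceptor distance is within ``d_max``,
    the angle at the donor against every covalent antecedent is at least
    ``antecedent_angle_min``, and — when the donor has exactly two
    antecedents, fixing the idealized in-plane H direction — the D-H...A
    angle is at least ``h_angle_min``.  Residues closer than
    ``min_separation`` on one chain are skipped unless both atoms are
    side-chain atoms.  Missing atoms silently skip candidate pairs.
    """
    donors = []
    for cid, res in s.iter_residues():
        for a in _donor_atoms(res):
            donors.append((cid, res, a))
    acceptors = []
    for cid, res in s.iter_residues():
        for a in _acceptor_atoms(res):
            acceptors.append((cid, res, a))
    out: list[Interaction] = []
    seen: set[tuple] = set()
    for cid_d, res_d, at_d in donors:
        for cid_a, res_a, at_a in acceptors:
            if cid_d == cid_a and res_d.number == res_a.number:
                continue
            d = float(np.linalg.norm(at_d.xyz - at_a.xyz))
            if d > criteria.d_max:
                continue
            if not _separation_ok(
                cid_d, res_d, at_d.name, cid_a, res_a, at_a.name,
                criteria.min_separation,
            ):
                continue
            ants = _antecedents(s, cid_d, res_d, at_d)
            ok = all(
                _angle(ant, at_d.xyz, at_a.xyz) >= criteria.antecedent_angle_min
                for ant in ants
            )
            if not ok:
                continue
            angle = None
            if len(ants) == 2:
                u = ants[0] - at_d.xyz
                v = ants[1] - at_d.xyz
                u /= np.linalg.norm(u)
                v /= np.linalg.norm(v)
                h_dir = -(u + v)
                norm = np.linalg.norm(h_dir)
                if norm > 1e-6:
                    h = at_d.xyz + h_dir / norm  # idealized H at 1.0 A
                    angle = _angle(at_d.xyz, h, at_a.xyz)
                    if angle < criteria.h_angle_min:
                        continue
            pa = Partner(cid_d, res_d.number, res_d.name, at_d.name)
            pb = Partner(cid_a, res_a.number, res_a.name, at_a.name)
            if pb.key() < pa.key():
                pa, pb = pb, pa
            key = ("hbond", pa.key(), pb.key())
            if key in seen:
                continue
            seen.add(key)
            out.append(Interaction("hbond", pa, pb, d, angle, s.structure_id))
    return out


def detect_vdw(
    s: Structure, criteria: VdwCriteria = VdwCriteria()
) -> list[Interaction]:
    """Heavy-atom van der Waals contacts: distance <= r_a + r_b + tolerance.

    Pairs already reported as hydrogen bonds are excluded, as are
    near-covalent distances (< ``min_distance``) and residue pairs closer
    than ``min_separation`` unless both atoms are side-chain atoms.
    """
    hbond_pairs = {
        (i.partner_a.key(), i.partner_b.key()) for i in detect_hbonds(s)
    }
    entries = [
        (cid, res, a) for cid, res in s.iter_residues() for a in res.atoms.values()
    ]
    coords = np.array([e[2].pos for e in entries])
    out: list[Interaction] = []
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    max_cut = 2 * max(VDW_RADII.values()) + criteria.tolerance
    for i, j in sorted(tree.query_pairs(max_cut)):
        cid_i, res_i, at_i = entries[i]
        cid_j, res_j, at_j = entries[j]
        if cid_i == cid_j and res_i.number == res_j.number:
            continue
        d = float(np.linalg.norm(at_i.xyz - at_j.xyz))
        cut = (
            VDW_RADII.get(at_i.element, DEFAULT_VDW_RADIUS)
            + VDW_RADII.get(at_j.element, DEFAULT_VDW_RADIUS)
            + criteria.tolerance
        )
        if d > cut or d < criteria.min_distance:
            continue
        if not _separation_ok(
            cid_i, res_i, at_i.name, cid_j, res_j, at_j.name,
            criteria.min_separation,
        ):
            continue
        pa = Partner(cid_i, res_i.number, res_i.name, at_i.name)
        pb = Partner(cid_j, res_j.number, res_j.name, at_j.name)
        if pb.key() < pa.key():
            pa, pb = pb, pa
        if (pa.key(), pb.key()) in hbond_pairs:
            continue
        out.append(Interaction("vdw", pa, pb, d, None, s.structure_id))
    return out


def detect_chpi(
    s: Structure, criteria: ChPiCriteria = ChPiCriteria()
) -> list[Interaction]:
    """Carbon to aromatic-ring-centroid CH-pi interactions.

    A carbon from another residue interacts with a Phe/Tyr/His/Trp ring when
    its distance to the ring centroid is within ``d_max`` and its elevation
    angle above the ring plane is at least ``elevation_min`` degrees.
    """
    rings = []
    for cid, res in s.iter_residues():
        for ring_atoms in AROMATIC_RINGS.get(res.name, ()):
            atoms = [res.atom(n) for n in ring_atoms]
            if any(a is None for a in atoms):
                continue  # incomplete ring
            coords = np.array([a.pos for a in atoms])
            centroid = coords.mean(axis=0)
            centered = coords - centroid
            # ring normal: smallest singular vector
            _, _, vt = np.linalg.svd(centered)
            normal = vt[2]
            desc = f"ring({ring_atoms[0]}-{ring_atoms[-1]})"
            rings.append((cid, res, centroid, normal, desc))
    out: list[Interaction] = []
    for cid_c, res_c in s.iter_residues():
        for at in res_c.atoms.values():
            if at.element != "C":
                continue
            for cid_r, res_r, centroid, normal, desc in rings:
                if cid_c == cid_r and res_c.number == res_r.number:
                    continue
                v = at.xyz - centroid
                d = float(np.linalg.norm(v))
                if d > criteria.d_max or d < 1e-6:
                    continue
                elevation = math.degrees(math.asin(abs(float(np.dot(v / d, normal)))))
                if elevation < criteria.elevation_min:
                    continue
                pa = Partner(cid_c, res_c.number, res_c.name, at.name)
                pb = Partner(cid_r, res_r.number, res_r.name, desc)
                out.append(
                    Interaction("chpi", pa, pb, d, elevation, s.structure_id)
                )
    return out


ALL_DETECTORS = {"hbond": detect_hbonds, "vdw": detect_vdw, "chpi": detect_chpi}


# ---------------------------------------------------------------------------
# Ensemble frequencies


@dataclass
class EnsembleTable:
    """Interaction occurrence across a structure ensemble.

    One row per (kind, residue-pair in reference numbering): the structures
    where the interaction is present, the denominator (structures where both
    positions are resolved), and the resulting frequency, optionally
    stratified by state label.  ``coverage`` records, per reference position,
    the structures in which it is missing (disordered).
    """

    rows: pd.DataFrame
    coverage: pd.DataFrame
    n_structures: int

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def coverage_to_tsv(self, path: str | Path) -> None:
        self.coverage.to_csv(path, sep="\t", index=False)


def ensemble_frequency(
    structures: Sequence[Structure],
    positions: Iterable[int],
    seq_offsets: Mapping[str, int] | None = None,
    kinds: Sequence[str] = ("hbond", "vdw", "chpi"),
) -> EnsembleTable:
    """Frequency of each interaction touching ``positions`` across structures.

    ``positions`` are reference residue numbers; ``seq_offsets`` maps each
    structure id to the offset such that ``refpos = author_number + offset``
    (default 0).  Interactions are keyed at residue-pair level in reference
    numbering (chains collapsed).  A structure enters a pair's denominator
    only when both positions are resolved in it; missing positions are listed
    in the coverage report.  Per-state frequencies use the structures'
    ``state_label``.
    """
    if not structures:
        raise ValueError("need at least one structure")
    positions = set(int(p) for p in positions)
    seq_offsets = dict(seq_offsets or {})
    present_map: dict[str, set[int]] = {}
    inter_map: dict[tuple, set[str]] = {}
    for s in structures:
        off = seq_offsets.get(s.structure_id, 0)
        resolved = {
            num + off
            for chain in s.chains.values()
            for num in chain.residues
        }
        present_map[s.structure_id] = resolved & positions
        for kind in kinds:
            for inter in ALL_DETECTORS[kind](s):
                (ca, na), (cb, nb) = inter.residue_pair()
                pa, pb = na + off, nb + off
                if pa > pb:
                    pa, pb = pb, pa
                if pa not in positions and pb not in positions:
                    continue
                inter_map.setdefault((kind, pa, pb), set()).add(s.structure_id)
    state_of = {s.structure_id: s.state_label for s in structures}
    rows = []
    for (kind, pa, pb), present_in in sorted(inter_map.items()):
        both_resolved = [
            s.structure_id
            for s in structures
            if _resolved(s, pa, seq_offsets) and _resolved(s, pb, seq_offsets)
        ]
        n_total = len(both_resolved)
        n_present = len(present_in & set(both_resolved))
        row = {
            "kind": kind,
            "pos_a": pa,
            "pos_b": pb,
            "n_present": n_present,
            "n_total": n_total,
            "frequency": n_present / n_total if n_total else float("nan"),
            "structure_ids": ",".join(sorted(present_in)),
        }
        for state in ("active", "inactive"):
            denom = [sid for sid in both_resolved if state_of[sid] == state]
            num = len(present_in & set(denom))
            row[f"freq_{state}"] = num / len(denom) if denom else float("nan")
        rows.append(row)
    cov_rows = []
    for pos in sorted(positions):
        missing = [
            s.structure_id
            for s in structures
            if not _resolved(s, pos, seq_offsets)
        ]
        cov_rows.append(
            {
                "refpos": pos,
                "n_missing": len(missing),
                "missing_in": ",".join(missing),
            }
        )
    columns = [
        "kind", "pos_a", "pos_b", "n_present", "n_total", "frequency",
        "freq_active", "freq_inactive", "structure_ids",
    ]
    rows_df = pd.DataFrame(rows, columns=columns)
    cov_df = pd.DataFrame(cov_rows, columns=["refpos", "n_missing", "missing_in"])
    return EnsembleTable(rows_df, cov_df, len(structures))


def _resolved(s: Structure, refpos: int, seq_offsets: Mapping[str, int]) -> bool:
    off = seq_offsets.get(s.structure_id, 0)
    return s.has_residue_number(refpos - off)


# ---------------------------------------------------------------------------
# Tether classification


@dataclass(frozen=True)
class TetherAnnotation:
    """Reference position -> (region label, tether class NLT/AST/CLT/none)."""

    regions: Mapping[int, tuple[str, str]]

    VALID_CLASSES = frozenset({"NLT", "AST", "CLT", "none"})

    def __post_init__(self) -> None:
        for pos, (region, cls) in self.regions.items():
            if cls not in self.VALID_CLASSES:
                raise ValueError(f"unknown tether class {cls!r} at {pos}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TetherAnnotation":
        """TSV with columns refpos, region, tether_class (header optional)."""
        regions: dict[int, tuple[str, str]] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            if ln == 1 and not parts[0].strip().lstrip("-").isdigit():
                continue  # header
            regions[int(parts[0])] = (parts[1].strip(), parts[2].strip())
        return cls(regions)


def classify_tethers(
    result: ContrastResults, annot: TetherAnnotation
) -> pd.DataFrame:
    """Join selected pattern positions with their region and tether class.

    Selected positions absent from the annotation get region '' and class
    'none'.  Purely a deterministic join; returns one row per selected
    position with a reference number.
    """
    rows = []
    for call in result.calls:
        if not call.selected or call.refpos is None:
            continue
        region, cls = annot.regions.get(call.refpos, ("", "none"))
        rows.append(
            {
                "refpos": call.refpos,
                "column": call.column,
                "pattern_set": call.pattern_str,
                "score": call.score,
                "region": region,
                "tether_class": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["refpos", "column", "pattern_set", "score", "region", "tether_class"],
    )
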