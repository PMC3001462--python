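"""Synthetic data with planted ground truth for every pipeline stage.

Three generators, all seed-deterministic, all emitting the standard formats
the pipeline readers consume:

* :func:`generate_msa` — a foreground/background alignment with planted
  family-specific pattern columns at a stated conservation level, optional
  gaps and duplicated foreground clones (to exercise sequence weighting).
  Sequences are i.i.d. given column profiles; there is no phylogeny — the
  statistics under test are profile-level, and the duplicate-clone mechanism
  stands in for tree correlation where weighting matters.
* :func:`generate_helix` — an ideal poly-alanine alpha-helix with the
  i -> i+4 backbone hydrogen-bond list as truth.
* :func:`generate_mutation_fixture` — a mutation table whose overlap with a
  designated pattern-position set is exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment import AMINO_ACIDS, Alignment, GAP
from .contrast import PartitionSpec
from .mutations import MutationRecord
from .structure import Atom, Chain, Residue, Structure


class SyntheticConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class SyntheticMSAConfig:
    """Study conditions for the synthetic foreground/background alignment.

    Defaults are the benchmark conditions used throughout the test suite:
    50 foreground vs 200 background sequences over 100 columns with 10
    planted pattern columns conserved at 0.9 in the foreground against a
    background frequency of 0.05, a light gap rate, and no clones.
    """

    n_fore: int = 50
    n_back: int = 200
    L: int = 100
    n_pattern_columns: int = 10
    pattern_columns: tuple[int, ...] | None = None  # default: sampled
    theta_fore: float = 0.9
    p_back_pattern: float = 0.05
    background_concentration: float = 0.5  # Dirichlet over the 20 letters
    gap_rate: float = 0.02
    n_duplicate_clones: int = 0

    def __post_init__(self) -> None:
        if self.n_fore < 2 or self.n_back < 2 or self.L < 1:
            raise SyntheticConfigError("need n_fore, n_back >= 2 and L >= 1")
        if not 0 <= self.p_back_pattern < self.theta_fore <= 1:
            raise SyntheticConfigError(
                "need 0 <= p_back_pattern < theta_fore <= 1"
            )
        if not 0 <= self.gap_rate < 1:
            raise SyntheticConfigError("gap_rate must be in [0, 1)")
        if self.pattern_columns is not None:
            if any(not 0 <= c < self.L for c in self.pattern_columns):
                raise SyntheticConfigError("pattern_columns outside [0, L)")
        elif self.n_pattern_columns > self.L:
            raise SyntheticConfigError("more pattern columns than columns")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth sufficient to score recovery directly."""

    pattern_columns: dict[int, str] = field(default_factory=dict)  # col -> residue
    class_labels: dict[str, str] = field(default_factory=dict)  # id -> fore/back
    hbond_pairs: tuple[tuple[int, int], ...] = ()  # residue numbers (O_i, N_j)
    contingency: tuple[tuple[int, int], tuple[int, int]] | None = None
    pattern_positions: tuple[int, ...] = ()
    mutated_positions: tuple[int, ...] = ()


def generate_msa(
    cfg: SyntheticMSAConfig = SyntheticMSAConfig(), seed: int = 0
) -> tuple[Alignment, PartitionSpec, SyntheticTruth]:
    """Sample a foreground/background alignment with planted pattern columns.

    Per column a background residue profile is drawn from a symmetric
    Dirichlet.  Non-pattern columns: both classes sample i.i.d. from it.
    Pattern columns: the background profile is adjusted so the planted
    residue has frequency ``p_back_pattern`` (remainder renormalized);
    foreground sequences carry the planted residue with probability
    ``theta_fore`` and otherwise sample from the adjusted profile.  Gaps are
    inserted i.i.d.; clones are exact copies of randomly chosen foreground
    sequences, appended with ids suffixed ``_dupK``.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    if cfg.pattern_columns is not None:
        pattern_cols = sorted(set(cfg.pattern_columns))
    else:
        pattern_cols = sorted(
            rng.choice(cfg.L, size=cfg.n_pattern_columns, replace=False).tolist()
        )
    profiles = rng.dirichlet(np.full(20, cfg.background_concentration), size=cfg.L)
    planted: dict[int, str] = {}
    fore_profiles = profiles.copy()
    back_profiles = profiles.copy()
    for col in pattern_cols:
        k = int(rng.integers(0, 20))
        planted[col] = str(aa[k])
        prof = profiles[col].copy()
        rest = 1.0 - prof[k]
        if rest <= 0:
            rest = 1e-12
        adj = prof * ((1.0 - cfg.p_back_pattern) / rest)
        adj[k] = cfg.p_back_pattern
        adj /= adj.sum()
        back_profiles[col] = adj
        fore_profiles[col] = adj  # non-planted draws use the adjusted profile

    def sample_class(n: int, is_fore: bool) -> list[str]:
        seqs = []
        for _ in range(n):
            chars = []
            for col in range(cfg.L):
                prof = fore_profiles[col] if is_fore else back_profiles[col]
                if is_fore and col in planted and rng.random() < cfg.theta_fore:
                    ch = planted[col]
                else:
                    ch = str(aa[rng.choice(20, p=prof)])
                if cfg.gap_rate > 0 and rng.random() < cfg.gap_rate:
                    ch = GAP
                chars.append(ch)
            seqs.append("".join(chars))
        return seqs

    fore_seqs = sample_class(cfg.n_fore, True)
    back_seqs = sample_class(cfg.n_back, False)
    width = max(4, len(str(max(cfg.n_fore, cfg.n_back))))
    records = [(f"fore_{i:0{width}d}", s) for i, s in enumerate(fore_seqs, 1)]
    records += [(f"back_{i:0{width}d}", s) for i, s in enumerate(back_seqs, 1)]
    for k in range(cfg.n_duplicate_clones):
        src = int(rng.integers(0, cfg.n_fore))
        sid, seq = records[src]
        records.append((f"{sid}_dup{k + 1}", seq))
    aln = Alignment(tuple(records))
    labels = {
        sid: ("fore" if sid.startswith("fore_") else "back") for sid, _ in records
    }
    part = PartitionSpec(labels)
    truth = SyntheticTruth(pattern_columns=planted, class_labels=labels)
    return aln, part, truth


# ---------------------------------------------------------------------------
# Ideal helix

_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_BONDS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
_ANGLES = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _nerf(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """Place atom d given chain a-b-c with internal coordinates (degrees)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def generate_helix(n_res: int) -> tuple[Structure, SyntheticTruth]:
    """Ideal poly-alanine alpha-helix (phi -57, psi -47, standard geometry).

    The truth lists the i -> i+4 backbone O...N hydrogen-bond pairs by
    residue number (1-based); an ``n_res`` helix has ``n_res - 4`` of them.
    """
    if n_res < 5:
        raise SyntheticConfigError("helix needs n_res >= 5")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BONDS["N-CA"], 0.0, 0.0])]
    ang = math.radians(_ANGLES["N-CA-C"])
    C = [CA[0] + _BONDS["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n_res):
        n_i = _nerf(N[i - 1], CA[i - 1], C[i - 1], _BONDS["C-N"], _ANGLES["CA-C-N"], _PSI)
        ca_i = _nerf(CA[i - 1], C[i - 1], n_i, _BONDS["N-CA"], _ANGLES["C-N-CA"], _OMEGA)
        c_i = _nerf(C[i - 1], n_i, ca_i, _BONDS["CA-C"], _ANGLES["N-CA-C"], _PHI)
        N.append(n_i)
        CA.append(ca_i)
        C.append(c_i)
    O = [
        _nerf(N[i], CA[i], C[i], _BONDS["C-O"], _ANGLES["CA-C-O"], _PSI + 180.0)
        for i in range(n_res)
    ]
    CB = [
        _nerf(C[i], N[i], CA[i], _BONDS["CA-CB"], 110.5, 122.7)
        for i in range(n_res)
    ]
    residues: dict[int, Residue] = {}
    for i in range(n_res):
        atoms = {
            "N": Atom("N", "N", tuple(N[i])),
            "CA": Atom("CA", "C", tuple(CA[i])),
            "C": Atom("C", "C", tuple(C[i])),
            "O": Atom("O", "O", tuple(O[i])),
            "CB": Atom("CB", "C", tuple(CB[i])),
        }
        residues[i + 1] = Residue(i + 1, "ALA", atoms)
    structure = Structure("ideal_helix", {"A": Chain("A", residues)})
    pairs = tuple((i, i + 4) for i in range(1, n_res - 3))
    return structure, SyntheticTruth(hbond_pairs=pairs)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a minimal single-model PDB file (ATOM records only)."""
    lines = []
    serial = 1
    for cid in sorted(structure.chains):
        chain = structure.chains[cid]
        for num in chain.sorted_numbers():
            res = chain.residues[num]
            for atom in res.atoms.values():
                x, y, z = atom.pos
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
                lines.append(
                    f"ATOM  {serial:>5} {name}{'':1}{res.name:<3} {cid}"
                    f"{num:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2}"
                )
                serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Mutation fixtures


def generate_mutation_fixture(
    n_positions: int,
    n_pattern: int,
    n_mut: int,
    overlap: int,
    seed: int = 0,
    start: int = 1,
) -> tuple[list[MutationRecord], tuple[int, ...], SyntheticTruth]:
    """A mutation table with an exact planted pattern/mutation overlap.

    Positions span ``[start, start + n_positions)``.  Returns the mutation
    records, the designated pattern-position set, and a truth carrying the
    2x2 contingency table ``((overlap, pattern-only), (mut-only, neither))``.
    """
    if overlap > min(n_pattern, n_mut):
        raise SyntheticConfigError("overlap exceeds min(n_pattern, n_mut)")
    if n_pattern + n_mut - overlap > n_positions:
        raise SyntheticConfigError("pattern + mutation sets do not fit")
    rng = np.random.default_rng(seed)
    positions = np.arange(start, start + n_positions)
    perm = rng.permutation(positions)
    pattern = sorted(int(p) for p in perm[:n_pattern])
    shared = rng.choice(pattern, size=overlap, replace=False) if overlap else []
    rest_pool = sorted(set(int(p) for p in positions) - set(pattern))
    others = rng.choice(rest_pool, size=n_mut - overlap, replace=False)
    mutated = sorted(int(p) for p in list(shared) + list(others))
    aa = list(AMINO_ACIDS)
    records = []
    for pos in mutated:
        wt = aa[int(rng.integers(0, 20))]
        variant = aa[int(rng.integers(0, 20))]
        while variant == wt:
            variant = aa[int(rng.integers(0, 20))]
        records.append(
            MutationRecord(
                int(pos), wt, variant, "synthetic", int(rng.integers(1, 50))
            )
        )
    a = overlap
    b = n_pattern - overlap
    c = n_mut - overlap
    d = n_positions - a - b - c
    truth = SyntheticTruth(
        contingency=((a, b), (c, d)),
        pattern_positions=tuple(pattern),
        mutated_positions=tuple(mutated),
    )
    return records, tuple(pattern), truth


def write_mutation_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\twt\tvariant\tsite\tcount\n")
        for r in records:
            fh.write(f"{r.refpos}\t{r.wt}\t{r.variant}\t{r.primary_site}\t{r.count}\n")
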