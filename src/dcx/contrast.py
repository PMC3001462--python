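"""Foreground/background divergence contrast with a ball-in-urn column statistic.

The model: an alignment is split into a foreground family (e.g. ErbB kinases)
and a background superfamily (the other receptor tyrosine kinases).  For each
alignment column we ask how surprising the foreground's conservation of a
small residue set is, given the background's composition — drawing weighted
foreground sequences as balls from an urn whose fraction of "pattern" balls
is the background frequency of the set.  The negative log10 of the binomial
upper-tail probability is the column's divergence score; columns whose score
and foreground conservation clear configured thresholds are the family's
pattern positions.

:class:`ContrastModel` holds the data (alignment, partition, weights,
reference map) and configuration; :meth:`ContrastModel.fit` returns a
:class:`ContrastResults` with per-column :class:`PatternCall` rows, the
normalised score histogram, a ``summary()`` table and TSV/JSON export.  When
no partition is given, :meth:`ContrastModel.sample_partition` infers one by a
Gibbs-style alternation between pattern selection and sequence reassignment.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import beta as beta_dist

from .alignment import (
    AMINO_ACIDS,
    Alignment,
    ReferenceMap,
    ResidueFrequency,
    WeightVector,
    column_profile,
    compute_weights,
    map_columns,
    read_alignment,
    read_partition_labels,
)

LOG10 = math.log(10.0)


class ConfigurationError(ValueError):
    """Invalid analysis configuration (empty class, exhausted foreground...)."""


# ---------------------------------------------------------------------------
# The ball-in-urn statistic

_GL = np.empty(0)  # gammaln(i + 1) lookup, grown on demand


def _gl_table(n: int) -> np.ndarray:
    global _GL
    if _GL.size < n + 1:
        size = max(n + 1, 2 * _GL.size, 1024)
        _GL = gammaln(np.arange(size, dtype=float) + 1.0)
    return _GL


def _log_pmf(i: np.ndarray, n: int, p: float) -> np.ndarray:
    gl = _gl_table(n)
    return gl[n] - gl[i] - gl[n - i] + i * math.log(p) + (n - i) * math.log1p(-p)


def _logsumexp(x: np.ndarray) -> float:
    m = float(x.max())
    return m + math.log(np.exp(x - m).sum())


def _binom_tail_log10(k: int, n: int, p: float) -> float:
    """-log10 P(X >= k), X ~ Binomial(n, p), via a log-space tail sum.

    When the tail mass exceeds 1/2, the complement head sum is used through
    log1p so that scores arbitrarily close to 0 keep full relative accuracy.
    """
    tail = _logsumexp(_log_pmf(np.arange(k, n + 1), n, p))
    if tail > math.log(0.5):
        head = _logsumexp(_log_pmf(np.arange(0, k), n, p))
        return max(0.0, -math.log1p(-math.exp(head)) / LOG10)
    return max(0.0, -tail / LOG10)


def ball_in_urn_score(
    n_match: float,
    n_total: float,
    p_back: float,
    *,
    continuous: bool = False,
) -> float:
    """Divergence score: -log10 of the binomial upper-tail probability.

    ``P(X >= k)`` with ``X ~ Binomial(n, p_back)`` where ``k``/``n`` are the
    weighted match/total counts rounded half-up.  Computed via a log-space
    tail sum (gammaln + logsumexp), stable far beyond where the plain tail
    probability underflows.  Returns 0 when ``n_match`` is 0 (the tail is the
    whole distribution).  With ``continuous=True`` the unrounded counts are
    used through the regularized incomplete beta function instead.
    """
    if not 0 <= p_back <= 1:
        raise ValueError(f"p_back must be in [0, 1], got {p_back}")
    if n_match < 0 or n_total < 0 or n_match > n_total + 1e-9:
        raise ValueError(f"need 0 <= n_match <= n_total, got {n_match}, {n_total}")
    if n_match <= 0:
        return 0.0
    if p_back >= 1.0:
        return 0.0
    if continuous:
        if p_back <= 0.0:
            return float("inf")
        # P(X >= k) = I_p(k, n-k+1), evaluated in log space.
        logp = beta_dist.logcdf(p_back, n_match, n_total - n_match + 1.0)
        return max(0.0, -logp / LOG10)
    n = int(math.floor(n_total + 0.5))
    k = min(int(math.floor(n_match + 0.5)), n)
    if k <= 0:
        return 0.0
    if p_back <= 0.0:
        return float("inf")
    return _binom_tail_log10(k, n, p_back)


# ---------------------------------------------------------------------------
# Configuration and result containers


@dataclass(frozen=True)
class ContrastConfig:
    """Tunable parameters of the contrast analysis.

    max_set_size
        Largest residue set considered for one column's pattern (default 3).
    score_threshold
        Minimum ball-in-urn score for a column to be selected (default 10.0,
        i.e. tail probability <= 1e-10).
    min_fore_conservation
        Minimum weighted foreground frequency of the pattern set (default 0.6).
    top_candidates
        The candidate enumeration considers all single residues plus every
        subset (sizes 2..max_set_size) of the ``top_candidates`` most frequent
        foreground residues (default 6).
    exhaustive
        Enumerate every residue subset of size <= max_set_size instead.
    continuous_tail
        Use the unrounded regularized-incomplete-beta tail.
    pseudocount
        Additive pseudocount for the sampler's class residue likelihoods.
    n_sweeps, n_restarts, init_fore_fraction, min_pattern_columns
        Partition-sampler controls: sweeps per restart, independent restarts,
        initial foreground fraction, and the minimum number of columns used
        for reassignment (topped up from the score ranking when fewer are
        selected).
    null_skip_factor, null_joint_factor
        Degenerate-partition diagnostic: when the best joint score is below
        ``null_skip_factor * score_threshold``, the sampler is re-run on a
        column-permuted copy of the alignment (which destroys any consistent
        split) and the partition is flagged degenerate unless the real joint
        score exceeds ``null_joint_factor`` times the permuted-null joint.
    """

    max_set_size: int = 3
    score_threshold: float = 10.0
    min_fore_conservation: float = 0.6
    top_candidates: int = 6
    exhaustive: bool = False
    continuous_tail: bool = False
    pseudocount: float = 0.5
    n_sweeps: int = 25
    n_restarts: int = 3
    init_fore_fraction: float = 0.5
    min_pattern_columns: int = 5
    null_skip_factor: float = 5.0
    null_joint_factor: float = 2.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PartitionSpec:
    """Foreground/background membership over alignment sequences."""

    membership: Mapping[str, str]  # id -> 'fore' | 'back'
    source: str = "given"  # 'given' | 'sampled'

    def __post_init__(self) -> None:
        bad = {v for v in self.membership.values()} - {"fore", "back"}
        if bad:
            raise ConfigurationError(f"unknown partition classes: {sorted(bad)}")

    @classmethod
    def from_labels(cls, labels: Mapping[str, str]) -> "PartitionSpec":
        """Build from {fore|back|query} labels; 'query' ids join the foreground."""
        return cls(
            {i: ("fore" if lab in {"fore", "query"} else "back") for i, lab in labels.items()}
        )

    @property
    def fore_ids(self) -> tuple[str, ...]:
        return tuple(i for i, c in self.membership.items() if c == "fore")

    @property
    def back_ids(self) -> tuple[str, ...]:
        return tuple(i for i, c in self.membership.items() if c == "back")

    def validate_for(self, aln: Alignment) -> None:
        missing = set(aln.ids) - set(self.membership)
        if missing:
            raise ConfigurationError(
                f"partition does not cover alignment ids: {sorted(missing)[:5]}..."
                if len(missing) > 5
                else f"partition does not cover alignment ids: {sorted(missing)}"
            )
        for cls_name, ids in (("fore", self.fore_ids), ("back", self.back_ids)):
            n = sum(1 for i in ids if i in set(aln.ids))
            if n < 2:
                raise ConfigurationError(
                    f"partition class {cls_name!r} has {n} sequences; need >= 2"
                )


@dataclass(frozen=True)
class PatternCall:
    """One column's best family-distinguishing residue set and its score."""

    column: int
    refpos: int | None
    pattern_set: frozenset[str]
    n_fore_match: float
    n_fore_total: float
    p_back: float
    score: float
    selected: bool

    @property
    def fore_match_fraction(self) -> float:
        if self.n_fore_total <= 0:
            return 0.0
        return self.n_fore_match / self.n_fore_total

    @property
    def pattern_str(self) -> str:
        return "".join(sorted(self.pattern_set))


@dataclass(frozen=True)
class StabilityReport:
    """Effect of removing a sequence group on the selected pattern positions."""

    removed_group: tuple[str, ...]
    jaccard_overlap: float
    selected_before: frozenset[int]
    selected_after: frozenset[int]
    score_deltas: np.ndarray  # per column, after - before

    def __post_init__(self) -> None:
        if not 0.0 <= self.jaccard_overlap <= 1.0 + 1e-12:
            raise ValueError("jaccard_overlap outside [0, 1]")


def _pattern_candidates(
    fore: ResidueFrequency, config: ContrastConfig
) -> list[frozenset[str]]:
    present = sorted(fore.freqs)
    if not present:
        return []
    if config.exhaustive:
        pool = list(AMINO_ACIDS)
        cands = [frozenset(c) for c in pool]
        for size in range(2, config.max_set_size + 1):
            cands.extend(frozenset(c) for c in itertools.combinations(pool, size))
        return cands
    cands = [frozenset((r,)) for r in present]
    top = sorted(present, key=lambda r: (-fore.freqs[r], r))[: config.top_candidates]
    for size in range(2, config.max_set_size + 1):
        cands.extend(frozenset(c) for c in itertools.combinations(top, size))
    return cands


def select_pattern(
    fore: ResidueFrequency,
    back: ResidueFrequency,
    n_fore_total: float,
    config: ContrastConfig = ContrastConfig(),
    *,
    p_floor: float = 0.0,
    refpos: int | None = None,
) -> PatternCall:
    """Best-scoring residue set for one column.

    Every candidate set is scored by :func:`ball_in_urn_score` with the
    weighted foreground match count against the (floored) background frequency
    of the set.  Ties break toward the smaller set, then alphabetically.  The
    call is ``selected`` when the score reaches ``score_threshold`` and the
    foreground conservation of the set reaches ``min_fore_conservation``.
    """
    candidates = _pattern_candidates(fore, config)
    if not candidates or n_fore_total <= 0:
        return PatternCall(
            fore.column, refpos, frozenset(), 0.0, max(n_fore_total, 0.0), 1.0, 0.0, False
        )
    best: tuple[float, int, str] | None = None
    best_call: PatternCall | None = None
    for cand in candidates:
        f_fore = fore.freq(cand)
        n_match = min(f_fore * n_fore_total, n_fore_total)
        p = min(max(back.freq(cand), p_floor), 1.0)  # guard float round-off
        score = ball_in_urn_score(
            n_match, n_fore_total, p, continuous=config.continuous_tail
        )
        key = (-score, len(cand), "".join(sorted(cand)))
        if best is None or key < best:
            best = key
            best_call = PatternCall(
                column=fore.column,
                refpos=refpos,
                pattern_set=cand,
                n_fore_match=n_match,
                n_fore_total=n_fore_total,
                p_back=p,
                score=score,
                selected=False,
            )
    assert best_call is not None
    selected = (
        best_call.score >= config.score_threshold
        and best_call.fore_match_fraction >= config.min_fore_conservation
    )
    return replace(best_call, selected=selected)


# ---------------------------------------------------------------------------
# Model / Results


class ContrastModel:
    """Foreground/background contrast model over a protein alignment.

    Parameters
    ----------
    alignment
        The gapped multiple sequence alignment.
    partition
        A :class:`PartitionSpec` (or ``id -> {fore|back}`` mapping).  May be
        omitted if the partition is to be inferred with
        :meth:`sample_partition`.
    weights
        ``'position_based'`` (default), ``'uniform'``, or a precomputed
        :class:`WeightVector`.
    reference_id, signal_peptide_offset
        Optional reference sequence for residue numbering; the offset shifts
        mature coordinates into pre-mature numbering (24 for EGFR's signal
        peptide).
    config
        A :class:`ContrastConfig`; defaults are used when omitted.
    """

    def __init__(
        self,
        alignment: Alignment,
        partition: PartitionSpec | Mapping[str, str] | None = None,
        *,
        weights: str | WeightVector = "position_based",
        reference_id: str | None = None,
        signal_peptide_offset: int = 24,
        config: ContrastConfig | None = None,
    ) -> None:
        self.alignment = alignment
        if partition is not None and not isinstance(partition, PartitionSpec):
            partition = PartitionSpec(dict(partition))
        self.partition = partition
        if isinstance(weights, WeightVector):
            if len(weights) != alignment.n_records:
                raise ValueError("weight vector length does not match alignment")
            self.weights = weights
        else:
            self.weights = compute_weights(alignment, weights)
        self.refmap: ReferenceMap | None = (
            map_columns(alignment, reference_id, signal_peptide_offset)
            if reference_id is not None
            else None
        )
        self.config = config or ContrastConfig()

    @classmethod
    def from_files(
        cls,
        alignment_path: str | Path,
        labels_path: str | Path | None = None,
        **kwargs,
    ) -> "ContrastModel":
        """Build from an alignment file and an optional partition-label TSV."""
        aln = read_alignment(alignment_path)
        part = (
            PartitionSpec.from_labels(read_partition_labels(labels_path))
            if labels_path is not None
            else None
        )
        return cls(aln, part, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _indices(self, part: PartitionSpec) -> tuple[list[int], list[int]]:
        id_to_idx = {i: k for k, (i, _) in enumerate(self.alignment.records)}
        fore = [id_to_idx[i] for i in part.fore_ids if i in id_to_idx]
        back = [id_to_idx[i] for i in part.back_ids if i in id_to_idx]
        return fore, back

    def _class_profiles(
        self, idx: Sequence[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Weighted residue frequency matrix (20 x L, non-gap-conditional)
        and per-column non-gap weight for a sequence subset."""
        codes = self.alignment.codes_matrix()[list(idx)]
        w = self.weights.weights[list(idx)]
        L = codes.shape[1]
        counts = np.zeros((20, L))
        valid = codes >= 0
        cols = np.broadcast_to(np.arange(L), codes.shape)
        wmat = np.broadcast_to(w[:, None], codes.shape)
        np.add.at(counts, (codes[valid], cols[valid]), wmat[valid])
        nongap = counts.sum(axis=0)
        freqs = np.divide(
            counts, nongap, out=np.zeros_like(counts), where=nongap > 0
        )
        return freqs, nongap

    def fit(self, partition: PartitionSpec | None = None) -> "ContrastResults":
        """Run the per-column contrast and return a :class:`ContrastResults`."""
        part = partition or self.partition
        if part is None:
            raise ConfigurationError(
                "no partition given; pass one or use sample_partition()"
            )
        part.validate_for(self.alignment)
        fore_idx, back_idx = self._indices(part)
        fore_freqs, fore_nongap = self._class_profiles(fore_idx)
        back_freqs, back_nongap = self._class_profiles(back_idx)
        aa = list(AMINO_ACIDS)
        calls: list[PatternCall] = []
        for col in range(self.alignment.n_columns):
            fp = ResidueFrequency(
                col,
                {aa[k]: fore_freqs[k, col] for k in np.flatnonzero(fore_freqs[:, col])},
                0.0,
            )
            bp = ResidueFrequency(
                col,
                {aa[k]: back_freqs[k, col] for k in np.flatnonzero(back_freqs[:, col])},
                0.0,
            )
            p_floor = 1.0 / (2.0 * max(float(back_nongap[col]), 1.0))
            refpos = self.refmap.refpos(col) if self.refmap else None
            calls.append(
                select_pattern(
                    fp,
                    bp,
                    float(fore_nongap[col]),
                    self.config,
                    p_floor=p_floor,
                    refpos=refpos,
                )
            )
        return ContrastResults(self, part, tuple(calls))

    # -- partition sampling --------------------------------------------------

    def sample_partition(self, seed: int) -> "ContrastResults":
        """Infer the foreground/background split by Gibbs-style alternation.

        Each sweep (i) fits the contrast under the current membership and
        (ii) reassigns every sequence to foreground or background with
        probability proportional to the product, over the current pattern
        columns, of the class residue likelihoods (weighted counts plus an
        additive pseudocount).  The best state by joint score (sum of selected
        column scores) over all restarts and sweeps is returned; the sweep
        trace is kept in ``results.diagnostics``.

        The first restart is initialised from the sign of the leading
        principal component of the one-hot sequence matrix (a cheap spectral
        guess at the two classes); the remaining restarts start from random
        assignments.  A restart stops early once a sweep changes no labels.

        A partition is flagged degenerate (``diagnostics['degenerate']``)
        when its joint score is not clearly above what the same optimisation
        achieves on a column-permuted copy of the alignment, which has no
        consistent split by construction.
        """
        if self.alignment.n_records < 10:
            raise ConfigurationError("partition sampling needs >= 10 sequences")
        cfg = self.config
        best_results, best_joint, trace = self._sample_core(seed)
        best_results, best_joint, polish_iters = self._icm_polish(best_results)
        null_joint = None
        degenerate = best_joint < cfg.score_threshold
        if not degenerate and best_joint < cfg.null_skip_factor * cfg.score_threshold:
            null_joint = self._null_joint(seed)
            degenerate = best_joint < cfg.null_joint_factor * max(
                null_joint, cfg.score_threshold
            )
        best_results.diagnostics = {
            "seed": seed,
            "trace": trace,
            "best_joint_score": best_joint,
            "polish_iterations": polish_iters,
            "null_joint_score": null_joint,
            "degenerate": degenerate,
        }
        return best_results

    def _null_joint(self, seed: int, n_permutations: int = 3) -> float:
        """Best joint score over column-permuted (signal-free) copies.

        The max over a few permutations estimates how far pure optimisation
        pressure can push the joint score without any real class structure.
        """
        rng = np.random.default_rng(seed + 7_654_321)
        best = 0.0
        for _ in range(n_permutations):
            mat = self.alignment.as_matrix().copy()
            for col in range(mat.shape[1]):
                rng.shuffle(mat[:, col])
            permuted = Alignment(
                tuple(
                    (sid, "".join(mat[i]))
                    for i, sid in enumerate(self.alignment.ids)
                )
            )
            null_model = ContrastModel(
                permuted, weights=self.weights.method, config=self.config
            )
            _, joint, _ = null_model._sample_core(int(rng.integers(0, 2**31 - 1)))
            best = max(best, joint)
        return best

    def _sample_core(
        self, seed: int
    ) -> tuple["ContrastResults", float, list[dict]]:
        cfg = self.config
        rng = np.random.default_rng(seed)
        ids = list(self.alignment.ids)
        n = len(ids)
        codes = self.alignment.codes_matrix()
        w = self.weights.weights
        best_joint = -math.inf
        best_results: ContrastResults | None = None
        trace: list[dict] = []
        for restart in range(cfg.n_restarts):
            rrng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            if restart == 0:
                is_fore = self._spectral_init(codes, rrng)
                self._ensure_two(is_fore, rrng)
                # the statistic is foreground-asymmetric: pick the better
                # orientation of the spectral split
                is_fore = self._orient(is_fore, ids)
            else:
                is_fore = rrng.random(n) < cfg.init_fore_fraction
            self._ensure_two(is_fore, rrng)
            for sweep in range(cfg.n_sweeps):
                part = PartitionSpec(
                    {ids[i]: ("fore" if is_fore[i] else "back") for i in range(n)},
                    source="sampled",
                )
                res = self.fit(part)
                scores = np.array([c.score for c in res.calls])
                sel = [c.column for c in res.calls if c.selected]
                joint = float(scores[sel].sum()) if sel else 0.0
                if joint > best_joint:
                    best_joint = joint
                    best_results = res
                trace.append(
                    {
                        "restart": restart,
                        "sweep": sweep,
                        "n_fore": int(is_fore.sum()),
                        "n_selected": len(sel),
                        "joint_score": joint,
                    }
                )
                delta = self._reassignment_delta(is_fore, scores, sel)
                p_fore = 1.0 / (1.0 + np.exp(-np.clip(delta, -500, 500)))
                new_fore = rrng.random(n) < p_fore
                self._ensure_two(new_fore, rrng)
                converged = bool(np.array_equal(new_fore, is_fore))
                is_fore = new_fore
                if converged:
                    break
        assert best_results is not None
        return best_results, best_joint, trace

    def _reassignment_delta(
        self, is_fore: np.ndarray, scores: np.ndarray, selected: Sequence[int]
    ) -> np.ndarray:
        """Per-sequence fore-vs-back log-likelihood difference over the
        current pattern columns (class residue frequencies with additive
        pseudocounts, plus the mixing-proportion prior)."""
        cfg = self.config
        codes = self.alignment.codes_matrix()
        w = self.weights.weights
        n = codes.shape[0]
        cols = list(selected)
        if len(cols) < cfg.min_pattern_columns:
            order = np.argsort(-scores)
            cols = sorted(set(cols) | set(order[: cfg.min_pattern_columns]))
        delta = np.zeros(n)
        alpha = cfg.pseudocount
        for col in cols:
            col_codes = codes[:, col]
            counts_f = np.zeros(20)
            counts_b = np.zeros(20)
            valid = col_codes >= 0
            np.add.at(counts_f, col_codes[valid & is_fore], w[valid & is_fore])
            np.add.at(counts_b, col_codes[valid & ~is_fore], w[valid & ~is_fore])
            lf = np.log(counts_f + alpha) - np.log(counts_f.sum() + 20 * alpha)
            lb = np.log(counts_b + alpha) - np.log(counts_b.sum() + 20 * alpha)
            delta[valid] += lf[col_codes[valid]] - lb[col_codes[valid]]
        nf = is_fore.sum()
        delta += math.log((nf + alpha) / (n - nf + alpha))
        return delta

    def _icm_polish(
        self, results: "ContrastResults", max_iterations: int = 20
    ) -> tuple["ContrastResults", float, int]:
        """Deterministic finish: hard MAP reassignment to a fixed point.

        The stochastic search may retain background sequences whose
        absorption happens to raise the joint score; iterated conditional
        modes under the same class-likelihood rule removes them, so the
        returned partition is a fixed point of the reassignment step.
        """
        ids = list(self.alignment.ids)
        n = len(ids)
        is_fore = np.array(
            [results.partition.membership[i] == "fore" for i in ids]
        )
        res = results
        iters = 0
        for iters in range(1, max_iterations + 1):
            scores = np.array([c.score for c in res.calls])
            sel = [c.column for c in res.calls if c.selected]
            delta = self._reassignment_delta(is_fore, scores, sel)
            new_fore = delta > 0
            for val in (True, False):  # keep both classes legal
                if (new_fore == val).sum() < 2:
                    order = np.argsort(delta if val else -delta)
                    new_fore[order[-2:]] = val
            if np.array_equal(new_fore, is_fore):
                break
            is_fore = new_fore
            part = PartitionSpec(
                {ids[i]: ("fore" if is_fore[i] else "back") for i in range(n)},
                source="sampled",
            )
            res = self.fit(part)
        scores = np.array([c.score for c in res.calls])
        sel = [c.column for c in res.calls if c.selected]
        joint = float(scores[sel].sum()) if sel else 0.0
        return res, joint, iters

    def _orient(self, is_fore: np.ndarray, ids: list[str]) -> np.ndarray:
        """Return ``is_fore`` or its complement, whichever yields the higher
        joint score when fitted."""
        best = None
        best_joint = -math.inf
        for cand in (is_fore, ~is_fore):
            if min(cand.sum(), (~cand).sum()) < 2:
                continue
            part = PartitionSpec(
                {ids[i]: ("fore" if cand[i] else "back") for i in range(len(ids))},
                source="sampled",
            )
            res = self.fit(part)
            joint = sum(c.score for c in res.calls if c.selected)
            # fall back to the strongest single column when nothing passes
            if joint == 0.0:
                joint = max(c.score for c in res.calls) / 1e6
            if joint > best_joint:
                best_joint = joint
                best = cand
        assert best is not None
        return best.copy()

    @staticmethod
    def _spectral_init(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Initial split: sign of the leading PC of the one-hot sequence matrix."""
        n, L = codes.shape
        onehot = np.zeros((n, 20 * L))
        rows = np.repeat(np.arange(n), L)
        valid = codes.ravel() >= 0
        flat_cols = (np.tile(np.arange(L), n) * 20 + np.clip(codes.ravel(), 0, None))
        onehot[rows[valid], flat_cols[valid]] = 1.0
        centered = onehot - onehot.mean(axis=0)
        # leading eigenvector of the sequence-sequence Gram matrix by power
        # iteration; random start (the constant vector is in the null space)
        gram = centered @ centered.T
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        for _ in range(50):
            v = gram @ v
            norm = np.linalg.norm(v)
            if norm < 1e-12:
                return np.arange(n) % 2 == 0
            v /= norm
        return v >= 0

    @staticmethod
    def _ensure_two(is_fore: np.ndarray, rng: np.random.Generator) -> None:
        n = is_fore.size
        for val in (True, False):
            while (is_fore == val).sum() < 2:
                pool = np.flatnonzero(is_fore != val)
                is_fore[rng.choice(pool)] = val

    # -- stability ------------------------------------------------------------

    def jackknife_stability(
        self, group: Iterable[str], partition: PartitionSpec | None = None
    ) -> StabilityReport:
        """Re-fit without a foreground subgroup and compare selected columns.

        Emulates the robustness check of dropping one subfamily (e.g. ErbB3)
        and re-running the analysis.  ``group`` must be a subset of the
        foreground; at least two foreground sequences must remain.
        """
        part = partition or self.partition
        if part is None:
            raise ConfigurationError("jackknife requires a partition")
        group = tuple(group)
        fore = set(part.fore_ids)
        if not set(group) <= fore:
            raise ConfigurationError("group must be a subset of the foreground")
        if len(fore - set(group)) < 2:
            raise ConfigurationError("removing group leaves < 2 foreground sequences")
        before = self.fit(part)
        keep_ids = [i for i in self.alignment.ids if i not in set(group)]
        sub_aln = self.alignment.subset(keep_ids)
        sub_part = PartitionSpec(
            {i: part.membership[i] for i in keep_ids}, source=part.source
        )
        sub_model = ContrastModel(
            sub_aln,
            sub_part,
            weights=self.weights.method,
            config=self.config,
        )
        if self.refmap is not None:
            sub_model.refmap = map_columns(
                sub_aln, self.refmap.reference_id, self.refmap.signal_peptide_offset
            )
        after = sub_model.fit()
        s_before = frozenset(before.selected_columns)
        s_after = frozenset(after.selected_columns)
        union = s_before | s_after
        jaccard = 1.0 if not union else len(s_before & s_after) / len(union)
        deltas = np.array(
            [a.score - b.score for a, b in zip(after.calls, before.calls)]
        )
        return StabilityReport(group, jaccard, s_before, s_after, deltas)


class ContrastResults:
    """Fitted per-column contrast: pattern calls, histogram, summaries."""

    def __init__(
        self,
        model: ContrastModel,
        partition: PartitionSpec,
        calls: tuple[PatternCall, ...],
    ) -> None:
        self.model = model
        self.partition = partition
        self.calls = calls
        self.diagnostics: dict = {}

    @property
    def config(self) -> ContrastConfig:
        return self.model.config

    @property
    def selected_columns(self) -> list[int]:
        return [c.column for c in self.calls if c.selected]

    @property
    def selected_refpos(self) -> list[int]:
        return [c.refpos for c in self.calls if c.selected and c.refpos is not None]

    @property
    def histogram(self) -> np.ndarray:
        """Per-column heights in [0, 1]: score / max selected score, 0 if unselected."""
        h = np.zeros(len(self.calls))
        sel = self.selected_columns
        if not sel:
            return h
        top = max(self.calls[c].score for c in sel)
        if top <= 0:
            return h
        for c in sel:
            h[c] = min(1.0, self.calls[c].score / top)
        return h

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "column": c.column,
                "refpos": c.refpos,
                "pattern_set": c.pattern_str,
                "n_fore_match": c.n_fore_match,
                "n_fore_total": c.n_fore_total,
                "p_back": c.p_back,
                "score": c.score,
                "selected": c.selected,
            }
            for c in self.calls
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def metadata(self) -> dict:
        return {
            "weights_method": self.model.weights.method,
            "effective_count": self.model.weights.effective_count,
            "n_fore": len(self.partition.fore_ids),
            "n_back": len(self.partition.back_ids),
            "partition_source": self.partition.source,
            "config": self.config.to_dict(),
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if k != "trace"
            },
        }

    def write_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2))

    def summary(self, top: int | None = None) -> str:
        """Human-readable table of selected pattern positions, best first."""
        sel = sorted(
            (c for c in self.calls if c.selected), key=lambda c: -c.score
        )
        if top is not None:
            sel = sel[:top]
        lines = [
            "Divergence contrast results",
            f"  foreground: {len(self.partition.fore_ids)} sequences "
            f"({self.partition.source})",
            f"  background: {len(self.partition.back_ids)} sequences",
            f"  effective sequences: {self.model.weights.effective_count:.1f} "
            f"({self.model.weights.method} weighting)",
            f"  selected pattern positions: {len(self.selected_columns)} "
            f"of {len(self.calls)} columns",
            "",
            f"{'column':>6} {'refpos':>6} {'pattern':>8} {'fore%':>6} "
            f"{'p_back':>8} {'score':>8}",
        ]
        for c in sel:
            ref = str(c.refpos) if c.refpos is not None else "-"
            lines.append(
                f"{c.column:>6} {ref:>6} {c.pattern_str:>8} "
                f"{100 * c.fore_match_fraction:>5.1f}% {c.p_back:>8.4f} "
                f"{c.score:>8.2f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ContrastResults: {len(self.selected_columns)} selected "
            f"of {len(self.calls)} columns>"
        )
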