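"""Candidate protein-target mapping by gapless proteome alignment.

The procedure maps a signature's peptides onto candidate antigens:

1. Each (linker-trimmed) peptide is slid, without gaps, over every offset
   of every protein; the best full-length placement is kept (ties go to the
   smallest offset).
2. Each best placement deposits its **total** score on every protein
   position it covers; the positionwise sum over peptides is the protein's
   score profile, and the protein summary is the profile maximum — so
   proteins where several signature peptides pile onto the same region rise
   to the top. (The alternative reading, summary = sum of per-peptide best
   scores, is available via ``summary="sum"``.)
3. Proteins are ranked by summary, and an empirical one-sided p-value per
   protein is estimated by redrawing same-sized peptide sets uniformly from
   the whole library: p = (1 + #{null summaries >= observed}) / (n_perm + 1),
   the add-one estimator, so p is never zero.

Scoring uses BLOSUM62 by default; the substitution model is configurable,
including a plain identity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .array_io import DEFAULT_LINKER, PeptideLibrary, ProteinRecord
from .signature_selection import PeptideSet


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue-pair scores over a fixed alphabet."""

    alphabet: str
    scores: np.ndarray  # (n, n) float

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        m = substitution_matrices.load("BLOSUM62")
        alphabet = str(m.alphabet)
        return cls(alphabet, np.asarray(m, dtype=float))

    @classmethod
    def identity(cls, match: float = 1.0, mismatch: float = 0.0,
                 alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> "SubstitutionMatrix":
        n = len(alphabet)
        scores = np.full((n, n), mismatch, dtype=float)
        np.fill_diagonal(scores, match)
        return cls(alphabet, scores)

    def encode(self, sequence: str) -> np.ndarray:
        codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        lut = np.full(128, -1, dtype=np.int64)
        for i, c in enumerate(self.alphabet):
            lut[ord(c)] = i
        out = lut[codes]
        if (out < 0).any():
            bad = sorted({c for c in sequence if c not in self.alphabet})
            raise ValueError(f"residues outside matrix alphabet: {bad}")
        return out

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.encode(a)[0], self.encode(b)[0]])


# ---------------------------------------------------------------------------
# Gapless local alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentPlacement:
    peptide_id: str
    protein_id: str
    offset: int  # 0-based start on the protein
    score: float
    per_position: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isclose(self.score, sum(self.per_position)):
            raise ValueError("placement score must equal the per-position sum")


def _placement_scores(
    pep_codes: np.ndarray, prot_codes: np.ndarray, matrix: SubstitutionMatrix
) -> np.ndarray:
    """Scores of every ungapped full-length placement (vector over offsets)."""
    L = len(pep_codes)
    windows = np.lib.stride_tricks.sliding_window_view(prot_codes, L)
    return matrix.scores[pep_codes[None, :], windows].sum(axis=1)


def gapless_local_align(
    peptide: str,
    protein: str,
    matrix: SubstitutionMatrix,
    peptide_id: str = "peptide",
    protein_id: str = "protein",
) -> AlignmentPlacement:
    """Best ungapped full-length placement of ``peptide`` on ``protein``.

    The peptide is expected already linker-trimmed. Ties between equal
    scoring offsets are broken toward the smallest offset.
    """
    if len(peptide) == 0:
        raise ValueError("empty peptide")
    if len(protein) < len(peptide):
        raise ValueError(
            f"protein {protein_id} shorter ({len(protein)}) than peptide ({len(peptide)})"
        )
    pep = matrix.encode(peptide)
    prot = matrix.encode(protein)
    scores = _placement_scores(pep, prot, matrix)
    offset = int(np.argmax(scores))  # argmax returns the first (smallest) maximizer
    per_pos = matrix.scores[pep, prot[offset:offset + len(pep)]]
    return AlignmentPlacement(
        peptide_id=peptide_id,
        protein_id=protein_id,
        offset=offset,
        score=float(scores[offset]),
        per_position=tuple(float(x) for x in per_pos),
    )


# ---------------------------------------------------------------------------
# Proteome scoring
# ---------------------------------------------------------------------------

@dataclass
class ProteinScore:
    protein_id: str
    profile: np.ndarray
    summary: float
    rank: int | None = None
    p_value: float | None = None


def _peptide_items(
    peptides: PeptideSet | PeptideLibrary | Iterable[tuple[str, str]],
    trim_linker: str | None,
) -> list[tuple[str, str]]:
    if isinstance(peptides, PeptideSet):
        seqs = peptides.sequences()
        if seqs is None:
            raise ValueError("peptide set carries no sequences")
        items = list(seqs.items())
    elif isinstance(peptides, PeptideLibrary):
        items = list(peptides.sequences.items())
    else:
        items = list(peptides)
    if not items:
        raise ValueError("no peptides to align")
    if trim_linker:
        n = len(trim_linker)
        trimmed = []
        for pid, seq in items:
            if seq.endswith(trim_linker):
                seq = seq[:-n]
            trimmed.append((pid, seq))
        items = trimmed
    return items


def _best_placements_batch(
    items: Sequence[tuple[str, str]],
    proteins: Sequence[ProteinRecord],
    matrix: SubstitutionMatrix,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized best placements for many peptides against many proteins.

    Returns (scores, offsets, lengths): arrays of shape
    (n_peptides, n_proteins), (n_peptides, n_proteins), (n_peptides,).
    Peptides are grouped by trimmed length so each group scores all protein
    windows in one fancy-indexing pass.
    """
    n_pep, n_prot = len(items), len(proteins)
    prot_codes = [matrix.encode(p.sequence) for p in proteins]
    scores = np.empty((n_pep, n_prot))
    offsets = np.empty((n_pep, n_prot), dtype=np.int64)
    lengths = np.array([len(seq) for _, seq in items], dtype=np.int64)

    by_len: dict[int, list[int]] = {}
    for i, (_, seq) in enumerate(items):
        by_len.setdefault(len(seq), []).append(i)

    for L, idxs in by_len.items():
        short = [proteins[j].protein_id for j in range(n_prot) if len(prot_codes[j]) < L]
        if short:
            raise ValueError(
                f"protein {short[0]} shorter than a {L}-residue peptide"
            )
        pep_mat = np.stack([matrix.encode(items[i][1]) for i in idxs])
        for j in range(n_prot):
            windows = np.lib.stride_tricks.sliding_window_view(prot_codes[j], L)
            for start in range(0, len(idxs), chunk):
                block = pep_mat[start:start + chunk]
                # (chunk, n_windows, L) lookup, summed over the window
                s = matrix.scores[block[:, None, :], windows[None, :, :]].sum(axis=2)
                best = s.argmax(axis=1)
                rows = idxs[start:start + chunk]
                scores[rows, j] = s[np.arange(len(block)), best]
                offsets[rows, j] = best
    return scores, offsets, lengths


def _profiles_from_placements(
    pep_rows: Sequence[int],
    scores: np.ndarray,
    offsets: np.ndarray,
    lengths: np.ndarray,
    proteins: Sequence[ProteinRecord],
) -> list[np.ndarray]:
    profiles = []
    for j, prot in enumerate(proteins):
        profile = np.zeros(len(prot))
        for i in pep_rows:
            o = offsets[i, j]
            profile[o:o + lengths[i]] += scores[i, j]
        profiles.append(profile)
    return profiles


def _summaries_from_placements(
    pep_rows: np.ndarray,
    scores: np.ndarray,
    offsets: np.ndarray,
    lengths: np.ndarray,
    proteins: Sequence[ProteinRecord],
    summary: str,
) -> np.ndarray:
    """Protein summaries for one peptide subset, without materializing profiles.

    For ``summary="max"`` the profile maximum is found by an event sweep over
    placement interval endpoints (O(k log k) per protein for k peptides).
    """
    if summary == "sum":
        return scores[pep_rows].sum(axis=0)
    out = np.empty(len(proteins))
    for j, prot in enumerate(proteins):
        s = scores[pep_rows, j]
        starts = offsets[pep_rows, j]
        ends = starts + lengths[pep_rows]
        events = np.concatenate([np.stack([starts, s], axis=1),
                                 np.stack([ends, -s], axis=1)])
        # at a position p the profile value is the running sum after all
        # end events (negative) and start events at p are applied
        order = np.lexsort((events[:, 1], events[:, 0]))
        running = np.cumsum(events[order, 1])
        best = running.max()
        if _union_length(starts, ends) < len(prot):
            best = max(best, 0.0)  # some position is uncovered, hence zero
        out[j] = best
    return out


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    order = np.argsort(starts)
    total = 0
    cur_start, cur_end = None, None
    for s, e in zip(starts[order], ends[order]):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return int(total)


def _rank(protein_scores: list[ProteinScore]) -> list[ProteinScore]:
    order = sorted(
        range(len(protein_scores)),
        key=lambda i: (-protein_scores[i].summary, protein_scores[i].protein_id),
    )
    for rank, i in enumerate(order, start=1):
        protein_scores[i].rank = rank
    return [protein_scores[i] for i in order]


def score_proteome(
    peptides: PeptideSet | Iterable[tuple[str, str]],
    proteome: Sequence[ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
    trim_linker: str | None = DEFAULT_LINKER,
    summary: str = "max",
) -> list[ProteinScore]:
    """Score every protein against a peptide set; returns proteins ranked by summary."""
    if not proteome:
        raise ValueError("empty proteome")
    if summary not in ("max", "sum"):
        raise ValueError(f"unknown summary {summary!r}")
    matrix = matrix or SubstitutionMatrix.blosum62()
    items = _peptide_items(peptides, trim_linker)
    scores, offsets, lengths = _best_placements_batch(items, proteome, matrix)
    rows = list(range(len(items)))
    profiles = _profiles_from_placements(rows, scores, offsets, lengths, proteome)
    out = []
    for j, (prot, profile) in enumerate(zip(proteome, profiles)):
        s = float(profile.max()) if summary == "max" else float(scores[:, j].sum())
        out.append(ProteinScore(prot.protein_id, profile, s))
    return _rank(out)


def empirical_pvalues(
    test: PeptideSet,
    library: PeptideLibrary,
    proteome: Sequence[ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
    n_perm: int = 200,
    seed: int = 0,
    trim_linker: str | None = DEFAULT_LINKER,
    summary: str = "max",
) -> list[ProteinScore]:
    """Ranked protein scores with permutation p-values against library redraws.

    For each of ``n_perm`` draws, |test| peptides are sampled uniformly
    without replacement from the library and all protein summaries are
    recomputed; per protein, p = (1 + #{null >= observed}) / (n_perm + 1).
    Deterministic per seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(test) > len(library):
        raise ValueError("test set larger than library")
    matrix = matrix or SubstitutionMatrix.blosum62()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(404,)))

    test_ids = list(test.members.index)
    lib_ids = list(library.ids)
    draw_rows = [
        rng.choice(len(lib_ids), size=len(test_ids), replace=False)
        for _ in range(n_perm)
    ]
    needed_lib = sorted({int(i) for rows in draw_rows for i in rows})
    lib_items = _peptide_items(library, trim_linker)
    items = _peptide_items(test, trim_linker) + [lib_items[i] for i in needed_lib]
    lib_pos = {orig: len(test_ids) + k for k, orig in enumerate(needed_lib)}

    scores, offsets, lengths = _best_placements_batch(items, proteome, matrix)

    obs_rows = np.arange(len(test_ids))
    observed = _summaries_from_placements(
        obs_rows, scores, offsets, lengths, proteome, summary
    )
    exceed = np.zeros(len(proteome))
    for rows in draw_rows:
        perm_rows = np.array([lib_pos[int(i)] for i in rows])
        null = _summaries_from_placements(
            perm_rows, scores, offsets, lengths, proteome, summary
        )
        exceed += null >= observed
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    profiles = _profiles_from_placements(
        list(obs_rows), scores, offsets, lengths, proteome
    )
    out = []
    for j, prot in enumerate(proteome):
        s = float(observed[j])
        out.append(ProteinScore(prot.protein_id, profiles[j], s, p_value=float(pvals[j])))
    return _rank(out)


def protein_score_table(protein_scores: Sequence[ProteinScore]) -> pd.DataFrame:
    """Ranked candidate-target table: protein_id, summary, rank, p_value."""
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in protein_scores],
            "summary": [p.summary for p in protein_scores],
            "rank": [p.rank for p in protein_scores],
            "p_value": [p.p_value for p in protein_scores],
        }
    )
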