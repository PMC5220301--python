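"""Residue coevolution scoring from a multiple sequence alignment.

Pair coupling is scored by mutual information with average-product
correction (MI-APC), computed from sequence-weighted, pseudocounted pair
frequencies, then standardised to z-scores over all unmasked column pairs so
that a single score threshold (default > 2.0) is meaningful across
alignments. Precomputed coupling tables from external inference tools can be
read in the same container. Hotspots are columns whose mapped structure
residue is solvent exposed and whose best pair score exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .sasa import SasaResult, relative_residue_sasa
from .structure import Structure

ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
_A_INDEX = {c: i for i, c in enumerate(ALPHABET)}
GAP = ALPHABET.index("-")


class MsaError(ValueError):
    pass


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaError("empty alignment")
        L = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != L:
                raise MsaError(f"ragged alignment: row {self.ids[i]!r} has "
                               f"length {len(row)} != {L}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    def to_indices(self) -> np.ndarray:
        out = np.empty((self.n, self.L), dtype=np.int8)
        for i, row in enumerate(self.rows):
            for j, c in enumerate(row):
                out[i, j] = _A_INDEX.get(c, GAP)
        return out


@dataclass
class CoevolutionMap:
    scores: np.ndarray                 # (L, L) standardized, symmetric; NaN masked
    masked_columns: np.ndarray         # bool (L,)
    column_to_residue: dict[int, tuple[str, int]] = field(default_factory=dict)
    hotspots: list[tuple[str, int]] = field(default_factory=list)

    def per_column_max(self) -> np.ndarray:
        s = np.where(np.isnan(self.scores), -np.inf, self.scores)
        np.fill_diagonal(s, -np.inf)
        return s.max(axis=1)

    def top_pairs(self, k: int = 10) -> list[tuple[int, int, float]]:
        L = self.scores.shape[0]
        iu, ju = np.triu_indices(L, k=1)
        vals = self.scores[iu, ju]
        ok = ~np.isnan(vals)
        order = np.argsort(vals[ok])[::-1][:k]
        iu, ju, vals = iu[ok], ju[ok], vals[ok]
        return [(int(iu[o]), int(ju[o]), float(vals[o])) for o in order]


def read_msa(path: str | Path, fmt: str | None = None) -> MSA:
    """Read an aligned FASTA or Stockholm file.

    Rows are uppercased and '.' gaps normalised to '-'. The format is
    inferred from the file unless given ('fasta' or 'stockholm').
    """
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:15]
        fmt = "stockholm" if head.startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper().replace(".", "-") for rec in aln]
    return MSA(ids=ids, rows=rows)


def sequence_weights(idx: np.ndarray, identity_threshold: float = 0.8
                     ) -> np.ndarray:
    """Standard redundancy weights: 1 / (number of sequences within the
    identity threshold, including self)."""
    n = idx.shape[0]
    same = (idx[:, None, :] == idx[None, :, :]).mean(axis=2)
    counts = (same >= identity_threshold).sum(axis=1)
    return 1.0 / counts


def coevolution_scores(msa: MSA, seq_identity: float = 0.8,
                       pseudocount: float = 0.5,
                       max_gap_fraction: float = 0.5) -> CoevolutionMap:
    """MI-APC coupling scores, z-standardised over unmasked pairs.

    Columns with gap fraction above ``max_gap_fraction`` are masked (their
    scores are NaN). MI uses weighted single/pair frequencies with a
    per-symbol pseudocount; the average-product correction
    ``APC_ij = MI_i. * MI_.j / MI_..`` removes phylogenetic/entropic bias.
    """
    if msa.n < 2:
        raise MsaError("need at least 2 sequences")
    idx = msa.to_indices()
    L = msa.L
    gap_frac = (idx == GAP).mean(axis=0)
    masked = gap_frac > max_gap_fraction
    keep = np.flatnonzero(~masked)
    if keep.size == 0:
        raise MsaError("all columns masked by the gap filter")

    w = sequence_weights(idx, seq_identity)
    neff = w.sum()
    q = len(ALPHABET)
    onehot = np.zeros((msa.n, L, q))
    onehot[np.arange(msa.n)[:, None], np.arange(L)[None, :], idx] = 1.0
    wf = onehot * w[:, None, None]

    # single-column frequencies with pseudocount
    f1 = (wf.sum(axis=0) + pseudocount) / (neff + q * pseudocount)

    mi = np.zeros((L, L))
    for ai, i in enumerate(keep):
        xi = wf[:, i, :]
        for j in keep[ai + 1:]:
            fij = xi.T @ onehot[:, j, :]
            fij = (fij + pseudocount / q) / (neff + q * pseudocount)
            denom = np.outer(f1[i], f1[j])
            with np.errstate(divide="ignore", invalid="ignore"):
                term = fij * np.log(fij / denom)
            m = float(np.nansum(term))
            mi[i, j] = mi[j, i] = m

    # average-product correction over unmasked columns
    sub = mi[np.ix_(keep, keep)]
    row_mean = sub.sum(axis=1) / (keep.size - 1)
    total_mean = sub.sum() / (keep.size * (keep.size - 1))
    apc = np.outer(row_mean, row_mean) / total_mean if total_mean > 0 else 0.0
    corrected = sub - apc
    iu, ju = np.triu_indices(keep.size, k=1)
    vals = corrected[iu, ju]
    mu, sd = vals.mean(), vals.std(ddof=0)
    z = (corrected - mu) / sd if sd > 0 else np.zeros_like(corrected)

    scores = np.full((L, L), np.nan)
    scores[np.ix_(keep, keep)] = z
    np.fill_diagonal(scores, np.nan)
    return CoevolutionMap(scores=scores, masked_columns=masked)


def read_coupling_table(path: str | Path, L: int | None = None
                        ) -> CoevolutionMap:
    """Read a precomputed coupling table: TSV rows ``i<TAB>j<TAB>score``
    (1-based columns). Symmetrised; (i,j)/(j,i) duplicates must agree;
    missing pairs stay NaN (absent, not zero)."""
    path = Path(path)
    entries: dict[tuple[int, int], float] = {}
    max_col = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise MsaError(f"{path}:{lineno}: expected 'i j score'")
        i, j, s = int(parts[0]), int(parts[1]), float(parts[2])
        key = (min(i, j), max(i, j))
        if key in entries and not np.isclose(entries[key], s):
            raise MsaError(f"{path}:{lineno}: conflicting duplicate for pair "
                           f"{key}: {entries[key]} vs {s}")
        entries[key] = s
        max_col = max(max_col, i, j)
    L = L or max_col
    scores = np.full((L, L), np.nan)
    for (i, j), s in entries.items():
        scores[i - 1, j - 1] = scores[j - 1, i - 1] = s
    return CoevolutionMap(scores=scores,
                          masked_columns=np.zeros(L, dtype=bool))


def map_columns_to_residues(msa: MSA, structure: Structure, chain_id: str,
                            offset: int | None = None,
                            max_mismatch: float = 0.05) -> dict[int, tuple[str, int]]:
    """Map alignment columns to structure residues.

    The alignment consensus (most common non-gap symbol per column) is
    matched ungapped against the chain sequence; ``offset`` (consensus
    position of the chain's first residue) is found by scanning when not
    given. More than ``max_mismatch`` disagreement aborts.
    """
    idx = msa.to_indices()
    consensus = []
    cols = []
    for j in range(msa.L):
        col = idx[:, j]
        col = col[col != GAP]
        if col.size == 0:
            continue
        consensus.append(ALPHABET[np.bincount(col).argmax()])
        cols.append(j)
    cons = "".join(consensus)
    seq = structure.sequence(chain_id)
    residues = structure.chains[chain_id]

    def mismatch_at(off: int) -> float:
        n = min(len(seq), len(cons) - off)
        if n <= 0:
            return 1.0
        mm = sum(1 for k in range(n) if cons[off + k] != seq[k])
        return mm / n

    if offset is None:
        offset = min(range(max(1, len(cons) - len(seq) + 1)), key=mismatch_at)
    if mismatch_at(offset) > max_mismatch:
        raise MsaError(f"consensus/structure mismatch exceeds "
                       f"{max_mismatch:.0%} at offset {offset}")
    mapping = {}
    for k, r in enumerate(residues):
        pos = offset + k
        if 0 <= pos < len(cols):
            mapping[cols[pos]] = (chain_id, r.index)
    return mapping


def map_hotspots(cmap: CoevolutionMap, structure: Structure, sasa: SasaResult,
                 column_to_residue: dict[int, tuple[str, int]] | None = None,
                 score_cut: float = 2.0, exposure_cut: float = 0.25
                 ) -> list[tuple[str, int]]:
    """Surface coevolution hotspots: residues whose best pair score is
    strictly above ``score_cut`` and whose relative SASA is at least
    ``exposure_cut``. Unmappable columns are skipped (reported via the map),
    not fatal. The hotspot list is also stored on ``cmap``."""
    mapping = column_to_residue or cmap.column_to_residue
    if not mapping:
        raise MsaError("no column-to-residue mapping defined")
    best = cmap.per_column_max()
    resname = {r.key: r.name for r in structure.residues()}
    hot = []
    for col, key in mapping.items():
        if best[col] <= score_cut:        # strict > threshold
            continue
        area = sasa.per_residue_area.get(key)
        if area is None or key not in resname:
            continue
        if relative_residue_sasa(resname[key], area) >= exposure_cut:
            hot.append(key)
    cmap.column_to_residue = dict(mapping)
    cmap.hotspots = sorted(hot)
    return cmap.hotspots
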