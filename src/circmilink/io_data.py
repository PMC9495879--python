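"""Interaction tables, sequence catalogs, the bipartite adjacency, and
negative sampling.

The core object is :class:`InteractionDataset`: an ordered id universe for
each node class (circRNAs and miRNAs) plus the set of known positive pairs,
i.e. the edge list of the bipartite association graph. Ids are indexed in
order of first appearance so that index maps are deterministic without any
sorting assumption.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Full IUPAC nucleotide alphabet, RNA convention (T normalised to U on read).
IUPAC_NUCLEOTIDES = frozenset("ACGURYSWKMBDHVN")


@dataclass
class InteractionDataset:
    """Labelled bipartite edge list with id <-> index maps.

    ``positive_pairs`` holds (circ_index, mirna_index) tuples; negatives are
    sampled separately (see :func:`sample_negative_pairs`) and carry label 0.
    """

    circ_ids: list[str]
    mirna_ids: list[str]
    positive_pairs: set[tuple[int, int]]
    circ_index: dict[str, int] = field(init=False, repr=False)
    mirna_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise ValueError("duplicate circRNA ids")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids")
        overlap = set(self.circ_ids) & set(self.mirna_ids)
        if overlap:
            raise ValueError(f"ids appear in both node classes: {sorted(overlap)[:5]}")
        self.circ_index = {c: i for i, c in enumerate(self.circ_ids)}
        self.mirna_index = {m: j for j, m in enumerate(self.mirna_ids)}
        for i, j in self.positive_pairs:
            if not (0 <= i < self.n_circ and 0 <= j < self.n_mirna):
                raise ValueError(f"pair index out of bounds: ({i}, {j})")

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    def subset_pairs(self, pairs: set[tuple[int, int]]) -> "InteractionDataset":
        """Same id universe, restricted edge set (used by CV folds)."""
        return InteractionDataset(list(self.circ_ids), list(self.mirna_ids), set(pairs))


@dataclass
class BipartiteAdjacency:
    """Dense C x M binary matrix; rows follow circ_ids, columns mirna_ids."""

    matrix: np.ndarray
    circ_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape != (len(self.circ_ids), len(self.mirna_ids)):
            raise ValueError("adjacency shape inconsistent with id lists")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.matrix = m.astype(float)


def read_interaction_table(
    path: str | Path,
    delimiter: str | None = None,
    header: bool | None = None,
) -> InteractionDataset:
    """Read a two-column (circRNA id, miRNA id) table.

    Parameters
    ----------
    delimiter
        Field separator; autodetected (tab, else comma) when None.
    header
        Skip the first row when True; when None the first row is treated as
        a header iff either of its first two fields reappears nowhere as an
        id and the file has >1 row is not checked -- detection is simply
        whether the first row equals common header names or contains a field
        named like a column label ("circ"/"mirna"). Pass explicitly for odd
        inputs.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty interaction table")
    if delimiter is None:
        first = next(line for line in lines if line.strip())
        delimiter = "\t" if "\t" in first else ","

    rows: list[tuple[str, str, int]] = []
    for lineno, row in enumerate(csv.reader(lines, delimiter=delimiter), start=1):
        if not row or not any(f.strip() for f in row):
            continue
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {row!r}")
        rows.append((row[0].strip(), row[1].strip(), lineno))

    if header is None:
        a, b, _ = rows[0]
        header = any(tok in f.lower() for f in (a, b) for tok in ("circ", "mir")) and not any(
            c.isdigit() for c in a + b
        )
    if header:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows")

    circ_ids: list[str] = []
    mirna_ids: list[str] = []
    circ_index: dict[str, int] = {}
    mirna_index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_dup = 0
    for c, m, _lineno in rows:
        if c not in circ_index:
            circ_index[c] = len(circ_ids)
            circ_ids.append(c)
        if m not in mirna_index:
            mirna_index[m] = len(mirna_ids)
            mirna_ids.append(m)
        pair = (circ_index[c], mirna_index[m])
        if pair in pairs:
            n_dup += 1
        pairs.add(pair)
    if n_dup:
        logger.warning("%s: dropped %d duplicate pair(s)", path, n_dup)
    logger.info(
        "%s: %d pairs, %d circRNAs, %d miRNAs", path, len(pairs), len(circ_ids), len(mirna_ids)
    )
    return InteractionDataset(circ_ids, mirna_ids, pairs)


def write_interaction_table(ds: InteractionDataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write pairs (sorted by index for determinism); round-trips with
    :func:`read_interaction_table` up to id-order normalisation."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        for i, j in sorted(ds.positive_pairs):
            w.writerow([ds.circ_ids[i], ds.mirna_ids[j]])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> RNA sequence catalog.

    Sequences are upper-cased and T is mapped to U; any character outside
    the IUPAC nucleotide alphabet is an error, as are duplicate headers and
    empty records.
    """
    path = Path(path)
    catalog: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in catalog:
            raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(f"{path}: {rec.id!r} has non-IUPAC characters {sorted(bad)}")
        catalog[rec.id] = seq
    if not catalog:
        raise ValueError(f"{path}: no FASTA records")
    return catalog


def write_fasta(catalog: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in catalog.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def build_bipartite_adjacency(ds: InteractionDataset) -> BipartiteAdjacency:
    """B[i, j] = 1 iff circRNA i is a known partner of miRNA j."""
    B = np.zeros((ds.n_circ, ds.n_mirna))
    for i, j in ds.positive_pairs:
        B[i, j] = 1.0
    return BipartiteAdjacency(B, list(ds.circ_ids), list(ds.mirna_ids))


def sample_negative_pairs(
    ds: InteractionDataset,
    n: int,
    seed: int | np.random.Generator,
    exclude: set[tuple[int, int]] | None = None,
) -> set[tuple[int, int]]:
    """Draw ``n`` distinct non-edges uniformly without replacement.

    ``exclude`` removes extra pairs from the candidate pool (e.g. negatives
    already drawn for another fold split). Reproducible given a seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    forbidden = set(ds.positive_pairs)
    if exclude:
        forbidden |= exclude
    total = ds.n_circ * ds.n_mirna
    available = total - len(forbidden)
    if n > available:
        raise ValueError(f"requested {n} negatives but only {available} non-edges available")
    if n == 0:
        return set()
    if total <= 2_000_000:
        flat_forbidden = np.fromiter(
            (i * ds.n_mirna + j for i, j in forbidden), dtype=np.int64, count=len(forbidden)
        )
        pool = np.setdiff1d(np.arange(total, dtype=np.int64), flat_forbidden)
        chosen = rng.choice(pool, size=n, replace=False)
    else:  # rejection sampling for very large grids
        chosen_set: set[int] = set()
        flat_forbidden_set = {i * ds.n_mirna + j for i, j in forbidden}
        while len(chosen_set) < n:
            draw = rng.integers(0, total, size=2 * (n - len(chosen_set)))
            for v in draw:
                v = int(v)
                if v not in flat_forbidden_set and v not in chosen_set:
                    chosen_set.add(v)
                    if len(chosen_set) == n:
                        break
        chosen = np.fromiter(chosen_set, dtype=np.int64)
    negatives = {(int(v) // ds.n_mirna, int(v) % ds.n_mirna) for v in chosen}
    assert not negatives & ds.positive_pairs
    return negatives
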