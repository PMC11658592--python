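"""Sequence-derived feature blocks: composition and PSSM summaries.

Each protein becomes a fixed-length vector by concatenating named blocks:

* ``AAC``  — amino-acid composition, 20 residue frequencies;
* ``PAAC`` — pair (dipeptide) composition, 400 ordered-pair frequencies
  over overlapping dipeptides;
* ``PSSM_<iters>_<db>`` — a 20-dim summary of a position-specific scoring
  matrix produced externally by an iterative profile search (one or three
  iterations against a clustered reference database). PSSMs are consumed
  as precomputed ASCII profiles only; this package never runs the search.

Standardization (z-scoring per dimension) is fitted on a declared sample
subset so cross-validation folds can avoid test-set leakage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, IO, Mapping, Sequence

import numpy as np

from gosubset.dataset import STANDARD_RESIDUES

logger = logging.getLogger(__name__)

RESIDUES = sorted(STANDARD_RESIDUES)  # alphabetical, 20 letters
_RES_INDEX = {r: i for i, r in enumerate(RESIDUES)}
PAIR_NAMES = [a + b for a in RESIDUES for b in RESIDUES]

PSSM_VARIANTS = ("PSSM_1_u50", "PSSM_3_u50", "PSSM_1_u90", "PSSM_3_u90")


def aac(sequence: str, alphabet: Sequence[str] = RESIDUES) -> np.ndarray:
    """Relative frequency of each residue; sums to 1."""
    if not sequence:
        raise ValueError("empty sequence")
    idx = {r: i for i, r in enumerate(alphabet)}
    out = np.zeros(len(alphabet))
    for ch in sequence:
        out[idx[ch]] += 1
    return out / len(sequence)


def paac(sequence: str, alphabet: Sequence[str] = RESIDUES) -> np.ndarray:
    """Relative frequency of ordered residue pairs over the L-1 dipeptides."""
    if len(sequence) < 2:
        raise ValueError("sequence shorter than 2 residues has no dipeptides")
    k = len(alphabet)
    idx = {r: i for i, r in enumerate(alphabet)}
    out = np.zeros(k * k)
    for a, b in zip(sequence, sequence[1:]):
        out[idx[a] * k + idx[b]] += 1
    return out / (len(sequence) - 1)


# -- PSSM parsing and summarization ------------------------------------

_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Z])\s+(.*)$")


def read_pssm(stream: IO[str] | str, expected_sequence: str | None = None) -> tuple[np.ndarray, str]:
    """Parse a PSI-BLAST ASCII profile into (L x 20 log-odds matrix, residues).

    The standard layout has a header naming 20 log-odds columns followed by
    20 weighted-percentage columns; only the log-odds block is returned,
    in the file's own column order (A R N D C Q E G H I L K M F P S T W Y V).
    A residue column disagreeing with ``expected_sequence`` logs a warning
    and proceeds (profiles are often built from pre-cleaning sequences).
    """
    text = stream if isinstance(stream, str) else stream.read()
    rows: list[list[int]] = []
    residues: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        m = _PSSM_ROW.match(line)
        if not m:
            continue
        fields = m.group(3).split()
        numeric = []
        for f in fields:
            try:
                numeric.append(int(f))
            except ValueError:
                break
        if len(numeric) < 20:
            raise ValueError(f"PSSM line {lineno}: expected >= 20 integer columns, found {len(numeric)}")
        rows.append(numeric[:20])
        residues.append(m.group(2))
    if not rows:
        raise ValueError("no PSSM rows found; truncated or non-PSSM input")
    seq = "".join(residues)
    if expected_sequence is not None and seq != expected_sequence:
        logger.warning("PSSM residue column disagrees with sequence (%d vs %d residues)", len(seq), len(expected_sequence))
    return np.array(rows, dtype=int), seq


def sigmoid_mean(pssm: np.ndarray) -> np.ndarray:
    """Default 20-dim PSSM summary: column-wise mean of sigmoid(log-odds)."""
    return (1.0 / (1.0 + np.exp(-pssm.astype(float)))).mean(axis=0)


def pssm_features(pssm: np.ndarray, summary: Callable[[np.ndarray], np.ndarray] = sigmoid_mean) -> np.ndarray:
    """Summarize an L x 20 profile into a fixed-length vector (pluggable)."""
    if pssm.ndim != 2 or pssm.shape[0] < 1:
        raise ValueError("PSSM must be a non-empty L x 20 matrix")
    return np.asarray(summary(pssm), dtype=float)


#: Row used when a protein has no profile file: sigmoid(0) everywhere,
#: the neutral pre-standardization value, so sequence-only runs still work.
NEUTRAL_PSSM_ROW = np.full(20, 0.5)


# -- block assembly ----------------------------------------------------


@dataclass
class FeatureBlock:
    """Named block of per-protein feature dimensions (proteins x dim)."""

    name: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("block matrix must be 2-D")
        if np.isnan(self.matrix).any():
            raise ValueError(f"block {self.name} contains missing values")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FeatureMatrix:
    """Concatenated, optionally standardized feature blocks.

    ``values[i]`` is the vector for ``proteins[i]``. When ``standardized``,
    each dimension was z-scored with mean/SD estimated on the fitting
    sample subset only; constant dimensions map to all-zero.
    """

    proteins: list[str]
    block_names: list[str]
    block_dims: list[int]
    values: np.ndarray
    standardized: bool = False

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def rows(self, accessions: Sequence[str]) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.proteins)}
        return self.values[[index[a] for a in accessions]]

    def write_tsv(self, path) -> None:
        import pandas as pd

        cols = [f"{n}_{k}" for n, d in zip(self.block_names, self.block_dims) for k in range(d)]
        pd.DataFrame(self.values, index=self.proteins, columns=cols).to_csv(path, sep="\t")


def assemble(
    blocks: Sequence[FeatureBlock],
    proteins: Sequence[str],
    fit_sample_ids: Sequence[str] | None = None,
    standardize: bool = True,
) -> FeatureMatrix:
    """Standardize each block per dimension and concatenate in order.

    Mean and standard deviation are estimated on the rows named by
    ``fit_sample_ids`` (default: all proteins) and applied to every row, so
    a matrix fitted on training folds applies cleanly to held-out folds.
    Constant dimensions (zero variance on the fit subset) become all-zero.
    """
    n = len(proteins)
    for b in blocks:
        if b.matrix.shape[0] != n:
            raise ValueError(f"block {b.name}: {b.matrix.shape[0]} rows for {n} proteins")
    fit_ids = list(fit_sample_ids) if fit_sample_ids is not None else list(proteins)
    index = {p: i for i, p in enumerate(proteins)}
    fit_rows = [index[p] for p in fit_ids]

    parts = []
    for b in blocks:
        mat = b.matrix.astype(float)
        if standardize:
            mu = mat[fit_rows].mean(axis=0)
            sd = mat[fit_rows].std(axis=0)
            out = np.zeros_like(mat)
            nz = sd > 0
            out[:, nz] = (mat[:, nz] - mu[nz]) / sd[nz]
            parts.append(out)
        else:
            parts.append(mat)
    return FeatureMatrix(
        proteins=list(proteins),
        block_names=[b.name for b in blocks],
        block_dims=[b.dim for b in blocks],
        values=np.concatenate(parts, axis=1) if parts else np.zeros((n, 0)),
        standardized=standardize,
    )


def sequence_blocks(sequences: Mapping[str, str], proteins: Sequence[str]) -> list[FeatureBlock]:
    """AAC + PAAC blocks for an ordered protein list."""
    aac_rows = np.stack([aac(sequences[p]) for p in proteins])
    paac_rows = np.stack([paac(sequences[p]) for p in proteins])
    return [FeatureBlock("AAC", aac_rows), FeatureBlock("PAAC", paac_rows)]


def pssm_blocks(
    proteins: Sequence[str],
    path_template: str,
    variants: Sequence[str] = PSSM_VARIANTS,
    summary: Callable[[np.ndarray], np.ndarray] = sigmoid_mean,
) -> list[FeatureBlock]:
    """PSSM summary blocks from per-protein ASCII profiles.

    ``path_template`` is formatted with ``accession`` and ``variant``;
    missing files yield the neutral row with a logged warning.
    """
    import os

    blocks = []
    for variant in variants:
        rows = []
        for acc in proteins:
            path = path_template.format(accession=acc, variant=variant)
            if not os.path.exists(path):
                logger.warning("missing PSSM %s for %s; using neutral row", variant, acc)
                rows.append(NEUTRAL_PSSM_ROW.copy())
                continue
            with open(path) as fh:
                mat, _ = read_pssm(fh)
            rows.append(pssm_features(mat, summary))
        blocks.append(FeatureBlock(variant, np.stack(rows)))
    return blocks
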