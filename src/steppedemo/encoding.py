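"""Genotype-matrix -> fixed-size three-level image conversion for the CNN.

Pixels use -1 for the reference/ancestral state, +1 for the alternative/
derived state and 0 for missing genotypes.  Rows are grouped extrazonal
block first, then zonal; within each block rows are sorted by descending
count of +1 pixels (ties broken by original row index) to remove the
permutation nuisance that a row-exchangeable matrix would otherwise present
to a convolutional network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MISSING, GenotypeMatrix

__all__ = ["SnpImage", "encode_image", "decode_image"]

PIXEL_REF = -1
PIXEL_ALT = 1
PIXEL_MISSING = 0


@dataclass(frozen=True)
class SnpImage:
    """H x W int8 image with pixels in {-1, 0, +1}.

    ``lineage_block_boundary`` is the row index of the first zonal row.
    """

    pixels: np.ndarray
    lineage_block_boundary: int

    def __post_init__(self) -> None:
        if not np.isin(self.pixels, (-1, 0, 1)).all():
            raise ValueError("image pixels must be in {-1, 0, +1}")


def encode_image(
    gm: GenotypeMatrix,
    width: int,
    row_order: str = "sorted",
    column_order: str = "sorted",
) -> SnpImage:
    """Encode a genotype matrix as a fixed-width SNP image.

    Columns beyond ``width`` are dropped from the right; narrower matrices
    are padded on the right with 0 (the missing-pixel value).  With
    ``row_order="sorted"`` (default) rows within each lineage block are
    ordered by descending +1 count with ties broken by original row index;
    ``row_order="none"`` keeps rows as given, and ``row_order="within_column"``
    re-stacks each column of a lineage block into canonical bars (derived,
    then reference, then missing pixels) — the exchangeability reduction the
    CNN pipeline uses, since haplotype identity across unlinked loci is
    uninformative.

    RAD loci are unlinked, so the input column order is arbitrary; with
    ``column_order="sorted"`` (default) columns are arranged by their
    per-lineage derived-allele pattern (ascending derived fraction in the
    extrazonal block, then in the zonal block, then call counts).  This
    gives the column axis a frequency-spectrum organization, so that
    convolution along it sees structure rather than an exchangeable
    sequence of loci; ``column_order="none"`` keeps columns as given.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if row_order not in ("sorted", "none", "within_column"):
        raise ValueError("row_order must be 'sorted', 'none' or 'within_column'")
    if column_order not in ("sorted", "none"):
        raise ValueError("column_order must be 'sorted' or 'none'")
    if gm.n_rows == 0 or gm.n_sites == 0:
        raise ValueError("cannot encode an empty genotype matrix")
    vals = gm.values
    if column_order == "sorted":
        keys = []
        for lineage in ("Z", "EZ"):  # reversed: last lexsort key is primary
            block = vals[gm.row_lineages == lineage]
            called = (block != MISSING).sum(axis=0)
            derived = (block == 1).sum(axis=0)
            frac = np.where(called > 0, derived / np.maximum(called, 1), -1.0)
            keys += [called, derived, frac]
        vals = vals[:, np.lexsort(tuple(keys))]
    vals = vals[:, :width]
    pix = np.where(vals == MISSING, PIXEL_MISSING, np.where(vals == 1, PIXEL_ALT, PIXEL_REF))
    pix = pix.astype(np.int8)
    row_lin = gm.row_lineages
    blocks = []
    for lineage in ("EZ", "Z"):
        idx = np.flatnonzero(row_lin == lineage)
        if row_order == "sorted" and idx.size:
            counts = (pix[idx] == PIXEL_ALT).sum(axis=1)
            # descending +1 count; ties by row content so the image is
            # invariant to the input row permutation, then original index
            order = sorted(
                range(idx.size),
                key=lambda r: (-counts[r], pix[idx[r]].tobytes(), idx[r]),
            )
            blocks.append(pix[idx[order]])
        elif row_order == "within_column" and idx.size:
            # canonical stacked bars: per column, derived pixels first, then
            # reference, then missing.  Haplotype identity across unlinked
            # loci carries no information, and this renders each column's
            # (derived, called) counts as bar heights a convolution can read.
            block = pix[idx]
            n = block.shape[0]
            plus = (block == PIXEL_ALT).sum(axis=0)
            minus = (block == PIXEL_REF).sum(axis=0)
            rows = np.arange(n)[:, None]
            blocks.append(
                np.where(rows < plus, PIXEL_ALT,
                         np.where(rows < plus + minus, PIXEL_REF, PIXEL_MISSING)
                         ).astype(np.int8)
            )
        else:
            blocks.append(pix[idx])
    boundary = blocks[0].shape[0]
    pix = np.concatenate(blocks, axis=0)
    if pix.shape[1] < width:
        pad = np.zeros((pix.shape[0], width - pix.shape[1]), dtype=np.int8)
        pix = np.concatenate([pix, pad], axis=1)
    return SnpImage(pixels=pix, lineage_block_boundary=boundary)


def decode_image(img: SnpImage, n_sites: int | None = None) -> np.ndarray:
    """Map pixels back to {0, 1, MISSING} values (trimmed to ``n_sites`` columns)."""
    pix = img.pixels if n_sites is None else img.pixels[:, :n_sites]
    return np.where(pix == PIXEL_MISSING, MISSING, np.where(pix == PIXEL_ALT, 1, 0)).astype(np.int8)
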