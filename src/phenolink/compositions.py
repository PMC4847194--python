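"""Prevalence filtering, pseudocounts, the centered log-ratio transform, and rarefaction.

Sequencing counts are compositional: only relative information is meaningful,
so downstream linear models operate on clr-transformed data. A single
pseudocount added to the raw counts handles zeros before taking logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import OtuTable

log = logging.getLogger(__name__)


@dataclass
class ClrMatrix:
    """clr-transformed abundances, samples x OTUs; every row sums to zero."""

    values: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]
    pseudocount: float

    def __post_init__(self) -> None:
        rs = np.abs(self.values.sum(axis=1))
        if rs.size and rs.max() > 1e-8:
            raise ValueError("clr rows must sum to zero")


def filter_prevalence(table: OtuTable, min_fraction: float = 0.10) -> OtuTable:
    """Drop OTUs present (count > 0) in fewer than ``min_fraction`` of samples.

    The boundary is inclusive: an OTU present in exactly ``min_fraction`` of
    samples is retained, because only strictly rarer OTUs are discarded.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    presence = (table.counts > 0).mean(axis=0)
    keep = presence >= min_fraction
    if not keep.any():
        raise ValueError(
            f"no OTU reaches prevalence {min_fraction}; lower the threshold")
    dropped = int((~keep).sum())
    if dropped:
        log.info("prevalence filter removed %d/%d OTUs", dropped, table.n_otus)
    return table.select_otus(keep)


def clr_transform(table: OtuTable, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform of counts after adding a pseudocount.

    For sample i: ``clr_ij = ln(c_ij + pc) - mean_j ln(c_ij + pc)``. Because
    clr subtracts the per-sample mean log, working on counts rather than
    closed relative abundances changes nothing but a row constant.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logc = np.log(table.counts.astype(float) + pseudocount)
    vals = logc - logc.mean(axis=1, keepdims=True)
    return ClrMatrix(vals, list(table.otu_ids), list(table.sample_ids), pseudocount)


def clr_array(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """clr on a raw (samples x OTUs) count array; convenience for internal use."""
    logc = np.log(np.asarray(counts, dtype=float) + pseudocount)
    return logc - logc.mean(axis=1, keepdims=True)


def rarefy(table: OtuTable, depth: int = 1000, seed: int | None = 0) -> OtuTable:
    """Subsample each sample to exactly ``depth`` observations without replacement.

    Samples whose library size is below ``depth`` are dropped (logged). The
    per-sample draw is multivariate hypergeometric, so the expected rarefied
    count of an OTU is ``depth * count / total``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} observations")
    if (~keep).any():
        dropped = [table.sample_ids[i] for i in np.where(~keep)[0]]
        log.warning("rarefy dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    sub = table.select_samples(keep)
    out = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        row = sub.counts[i]
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(out, sub.sample_ids, sub.otu_ids,
                    list(sub.taxonomy) if sub.taxonomy is not None else None)
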