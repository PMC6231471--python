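"""Shared in-memory containers for the analysis chain.

The central object is :class:`GenotypeMatrix`: diploid alt-allele dosages
(0/1/2) for individuals x loci with an explicit missing-data sentinel.
Population membership is a plain mapping individual -> population name;
group membership (geographic cluster) is a mapping population -> group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls, individuals x loci.

    Parameters
    ----------
    calls
        ``(n_ind, n_loci)`` int8 array of alt-allele dosages in {0, 1, 2}
        with :data:`MISSING` (=-1) for no-calls.
    individual_ids, locus_ids
        Unique string identifiers for rows and columns.
    depth, gq
        Optional per-genotype sequencing depth and genotype quality layers,
        same shape as ``calls``.
    fragments
        Optional per-locus fragment label (GBS fragment / genomic block);
        used as the resampling unit by the block bootstrap.
    """

    calls: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    fragments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D individuals x loci array")
        n_ind, n_loci = self.calls.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length does not match calls rows")
        if len(self.locus_ids) != n_loci:
            raise ValueError("locus_ids length does not match calls columns")
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("individual_ids must be unique")
        if len(set(self.locus_ids)) != n_loci:
            raise ValueError("locus_ids must be unique")
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or MISSING")
        for name in ("depth", "gq"):
            layer = getattr(self, name)
            if layer is not None and np.asarray(layer).shape != self.calls.shape:
                raise ValueError(f"{name} layer shape does not match calls")
        if self.fragments is not None and len(self.fragments) != n_loci:
            raise ValueError("fragments must have one label per locus")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset (or reorder/resample) loci by positional index."""
        index = np.asarray(index)
        ids = [self.locus_ids[i] for i in index]
        if len(set(ids)) != len(ids):  # bootstrap resamples duplicate loci
            ids = [f"{lid}_{k}" for k, lid in enumerate(ids)]
        return GenotypeMatrix(
            calls=self.calls[:, index],
            individual_ids=list(self.individual_ids),
            locus_ids=ids,
            depth=None if self.depth is None else self.depth[:, index],
            gq=None if self.gq is None else self.gq[:, index],
            fragments=None if self.fragments is None else np.asarray(self.fragments)[index],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            calls=self.calls.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            fragments=None if self.fragments is None else np.asarray(self.fragments).copy(),
        )


@dataclass
class PopAlleleFreqs:
    """Per-population alt-allele frequencies with per-cell sample sizes.

    ``freqs`` is populations x loci; ``n_alleles`` holds the number of
    non-missing alleles (2 x genotyped individuals) behind each cell. Cells
    with zero sample size are NaN in ``freqs`` and flagged in ``empty``.
    """

    freqs: np.ndarray
    n_alleles: np.ndarray
    populations: list[str]
    locus_ids: list[str]

    @property
    def empty(self) -> np.ndarray:
        return self.n_alleles == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=self.populations, columns=self.locus_ids)


def popmap_groups(popmap: Mapping[str, str]) -> dict[str, list[str]]:
    """Invert an individual -> population mapping to population -> members."""
    out: dict[str, list[str]] = {}
    for ind, pop in popmap.items():
        out.setdefault(pop, []).append(ind)
    return out


def membership_indices(
    ids: Sequence[str], assignment: Mapping[str, str]
) -> tuple[list[str], list[np.ndarray]]:
    """Row indices of ``ids`` for each label of ``assignment`` (sorted labels).

    Raises if any id is missing from the assignment.
    """
    missing = [i for i in ids if i not in assignment]
    if missing:
        raise KeyError(f"ids absent from assignment: {missing[:5]}")
    labels = sorted(set(assignment[i] for i in ids))
    index = {v: k for k, v in enumerate(ids)}
    groups = [
        np.array([index[i] for i in ids if assignment[i] == lab], dtype=np.intp)
        for lab in labels
    ]
    return labels, groups
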