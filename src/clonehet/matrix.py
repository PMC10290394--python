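"""Loci x samples genotype-class matrix."""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import genotypes as gt
from .records import LocusRecord


class GenotypeMatrix:
    """Genotype classes for a set of loci across a set of samples.

    Rows are loci keyed by (scaffold, 1-based position); columns are
    samples. Values are the five genotype classes, stored internally as
    int8 codes. ``metadata`` optionally maps each sample to a region or
    grove label.
    """

    def __init__(
        self,
        codes: np.ndarray,
        loci: Sequence[tuple[str, int]],
        samples: Sequence[str],
        metadata: Mapping[str, str] | None = None,
    ) -> None:
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(loci), len(samples)):
            raise ValueError("codes shape does not match loci x samples")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus keys")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample names")
        self.codes = codes
        self.loci: list[tuple[str, int]] = [tuple(k) for k in loci]  # type: ignore[misc]
        self.samples: list[str] = list(samples)
        self.metadata: dict[str, str] = dict(metadata or {})

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[LocusRecord],
        metadata: Mapping[str, str] | None = None,
    ) -> "GenotypeMatrix":
        records = list(records)
        if not records:
            return cls(np.empty((0, 0), dtype=np.int8), [], [], metadata)
        samples = list(records[0].calls)
        loci = []
        codes = np.empty((len(records), len(samples)), dtype=np.int8)
        for i, rec in enumerate(records):
            if list(rec.calls) != samples:
                raise ValueError(f"inconsistent sample set at {rec.scaffold}:{rec.pos}")
            loci.append(rec.key)
            for j, s in enumerate(samples):
                codes[i, j] = gt.CODE[rec.calls[s].cls]
        return cls(codes, loci, samples, metadata)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, metadata: Mapping[str, str] | None = None
    ) -> "GenotypeMatrix":
        """Build from a DataFrame of class names, index (scaffold, pos)."""
        loci = [tuple(k) for k in frame.index]
        return cls(gt.to_codes(frame.to_numpy()), loci, list(frame.columns), metadata)

    # -- basic views --------------------------------------------------------

    @property
    def n_loci(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_tuples(self.loci, names=["scaffold", "pos"])
        return pd.DataFrame(gt.to_names(self.codes), index=index, columns=self.samples)

    def class_mask(self, cls: str) -> np.ndarray:
        """Boolean (loci x samples) mask for one genotype class."""
        return self.codes == gt.CODE[cls]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    # -- subsetting ---------------------------------------------------------

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return GenotypeMatrix(
            self.codes[idx],
            [self.loci[i] for i in idx],
            self.samples,
            self.metadata,
        )

    def drop_missing_loci(self) -> "GenotypeMatrix":
        """Remove loci with any MISSING call (the default missing policy)."""
        keep = ~(self.codes == gt.CODE[gt.MISSING]).any(axis=1)
        return self.subset_loci(keep)

    def missing_as_ref(self) -> "GenotypeMatrix":
        """Recode MISSING calls as REF (the permissive alternative)."""
        codes = self.codes.copy()
        codes[codes == gt.CODE[gt.MISSING]] = gt.CODE[gt.REF]
        return GenotypeMatrix(codes, self.loci, self.samples, self.metadata)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metadata: Mapping[str, str] | None = None) -> "GenotypeMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=[0, 1])
        frame.index = pd.MultiIndex.from_tuples(
            [(str(s), int(p)) for s, p in frame.index], names=["scaffold", "pos"]
        )
        return cls.from_frame(frame, metadata)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_loci} loci x {self.n_samples} samples)"
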