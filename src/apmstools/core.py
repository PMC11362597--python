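"""Shared data model for the AP-MS quantification pipeline.

The two central objects are :class:`ProteinQuantTable`, a protein-by-sample
MaxLFQ intensity matrix with an explicit missingness mask, and
:class:`StudyDesign`, the sample-to-condition map carrying replicate and
pairing structure (GTPγS/GDPβS pairs derive from the same lysate portion).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "ProteinQuantTable",
    "SampleInfo",
    "StudyDesign",
    "FormatError",
    "DesignError",
]


class FormatError(ValueError):
    """Raised when an input file does not match the expected tabular layout."""


class DesignError(ValueError):
    """Raised when a study design is internally inconsistent."""


class Condition(str, enum.Enum):
    """Experimental conditions of the pulldown / co-IP / loading designs."""

    GST_CTRL = "GST_CTRL"          # GST-only pulldown control
    BAIT_INTACT = "BAIT_INTACT"    # GST-bait pulldown from intact lysate
    BAIT_GTPGS = "BAIT_GTPGS"      # GST-bait pulldown, GTPγS-loaded lysate
    BAIT_GDPBS = "BAIT_GDPBS"      # GST-bait pulldown, GDPβS-loaded lysate
    IGG_CTRL = "IGG_CTRL"          # co-IP control IgG
    COIP_BAIT = "COIP_BAIT"        # co-IP with anti-bait antibody

    @classmethod
    def parse(cls, value: "str | Condition") -> "Condition":
        if isinstance(value, Condition):
            return value
        try:
            return cls(str(value).strip())
        except ValueError:
            raise DesignError(
                f"unknown condition {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


@dataclass
class ProteinQuantTable:
    """Protein-by-sample intensity matrix with missingness.

    Parameters
    ----------
    protein_ids
        Unique accession strings, one per row.
    intensities
        Matrix of intensities, shape ``(n_proteins, n_samples)``. On the
        ``linear`` scale every non-missing entry is strictly positive; the
        value stored at missing cells is arbitrary (conventionally 0 on the
        linear scale) and must never be read through the mask.
    sample_ids
        Column labels in file order.
    missing_mask
        Boolean matrix, ``True`` where the protein was not detected.
    gene_symbols
        Optional per-row gene symbols ("" where absent).
    scale_tag
        Either ``"linear"`` (raw MaxLFQ) or ``"log2"``.
    """

    protein_ids: list[str]
    intensities: np.ndarray
    sample_ids: list[str]
    missing_mask: np.ndarray
    gene_symbols: list[str] = field(default_factory=list)
    scale_tag: str = "linear"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_p, n_s = len(self.protein_ids), len(self.sample_ids)
        if self.intensities.shape != (n_p, n_s):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{n_p} proteins x {n_s} samples"
            )
        if self.missing_mask.shape != self.intensities.shape:
            raise ValueError("missing_mask shape differs from intensities")
        if self.scale_tag not in ("linear", "log2"):
            raise ValueError(f"scale_tag must be 'linear' or 'log2', got {self.scale_tag!r}")
        if not self.gene_symbols:
            self.gene_symbols = [""] * n_p
        if len(self.gene_symbols) != n_p:
            raise ValueError("gene_symbols length differs from protein_ids")
        seen: dict[str, int] = {}
        dups = []
        for pid in self.protein_ids:
            seen[pid] = seen.get(pid, 0) + 1
            if seen[pid] == 2:
                dups.append(pid)
        if dups:
            raise FormatError(f"duplicate protein ids: {dups}")
        if self.scale_tag == "linear":
            observed = self.intensities[~self.missing_mask]
            if observed.size and not np.all(observed > 0):
                raise ValueError("non-missing linear intensities must be > 0")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(
            protein_ids=list(self.protein_ids),
            intensities=self.intensities.copy(),
            sample_ids=list(self.sample_ids),
            missing_mask=self.missing_mask.copy(),
            gene_symbols=list(self.gene_symbols),
            scale_tag=self.scale_tag,
        )

    def row_index(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"protein {protein_id!r} not in table") from None

    def col_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def subset_proteins(self, keep: Sequence[int] | np.ndarray) -> "ProteinQuantTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ProteinQuantTable(
            protein_ids=[self.protein_ids[i] for i in keep],
            intensities=self.intensities[keep, :],
            sample_ids=list(self.sample_ids),
            missing_mask=self.missing_mask[keep, :],
            gene_symbols=[self.gene_symbols[i] for i in keep],
            scale_tag=self.scale_tag,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ProteinQuantTable":
        cols = [self.col_index(s) for s in sample_ids]
        return ProteinQuantTable(
            protein_ids=list(self.protein_ids),
            intensities=self.intensities[:, cols],
            sample_ids=[self.sample_ids[c] for c in cols],
            missing_mask=self.missing_mask[:, cols],
            gene_symbols=list(self.gene_symbols),
            scale_tag=self.scale_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        """Intensities as a DataFrame (NaN at missing cells)."""
        values = self.intensities.copy()
        values[self.missing_mask] = np.nan
        return pd.DataFrame(values, index=self.protein_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: Condition
    replicate: int
    pair_id: Optional[str] = None


class StudyDesign:
    """Validated collection of :class:`SampleInfo` records.

    Pairing rule: each ``pair_id`` links exactly one GTPγS-loaded and one
    GDPβS-loaded bait sample (the two pulldowns from one lysate portion).
    """

    def __init__(self, samples: Sequence[SampleInfo]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        dup = sorted({i for i in ids if ids.count(i) > 1})
        if dup:
            raise DesignError(f"duplicate sample ids in design: {dup}")
        for s in samples:
            if s.replicate < 1:
                raise DesignError(f"sample {s.sample_id}: replicate must be >= 1")
        pairs: dict[str, list[SampleInfo]] = {}
        for s in samples:
            if s.pair_id is not None:
                pairs.setdefault(s.pair_id, []).append(s)
        for pid, members in pairs.items():
            conds = sorted(m.condition.value for m in members)
            if conds != [Condition.BAIT_GDPBS.value, Condition.BAIT_GTPGS.value]:
                raise DesignError(
                    f"pair {pid!r} must link exactly one BAIT_GTPGS and one "
                    f"BAIT_GDPBS sample, got {conds}"
                )
        self.samples = samples
        self._by_id = {s.sample_id: s for s in samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def conditions(self) -> list[Condition]:
        return sorted({s.condition for s in self.samples}, key=lambda c: c.value)

    def condition_of(self, sample_id: str) -> Condition:
        try:
            return self._by_id[sample_id].condition
        except KeyError:
            raise DesignError(f"sample {sample_id!r} not in design") from None

    def samples_in(self, condition: "str | Condition") -> list[str]:
        condition = Condition.parse(condition)
        return [s.sample_id for s in self.samples if s.condition == condition]

    def pairs(self) -> list[tuple[str, str]]:
        """(GTPγS sample, GDPβS sample) tuples, ordered by pair id."""
        grouped: dict[str, dict[Condition, str]] = {}
        for s in self.samples:
            if s.pair_id is not None:
                grouped.setdefault(s.pair_id, {})[s.condition] = s.sample_id
        return [
            (m[Condition.BAIT_GTPGS], m[Condition.BAIT_GDPBS])
            for _, m in sorted(grouped.items())
        ]

    def validate_against(self, table: ProteinQuantTable) -> None:
        """Every table sample must appear exactly once in the design."""
        missing = [s for s in table.sample_ids if s not in self._by_id]
        if missing:
            raise DesignError(f"samples missing from design: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition.value for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "pair_id": [s.pair_id if s.pair_id is not None else "" for s in self.samples],
            }
        )
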