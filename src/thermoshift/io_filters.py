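"""Reading MaxQuant-style proteinGroups tables and the protein-level QC cascade.

The quantitative input is the protein-level output of an isobaric-label
database search: one row per protein group with decoy / contaminant /
identified-only-by-site flags, a unique-peptide count, and one corrected
reporter-intensity column per TMT channel.  The QC cascade removes, in order:

1. flagged rows (reverse-database decoys, potential contaminants, proteins
   identified only by a modification site),
2. proteins quantified with fewer than two unique peptides,
3. proteins without a positive signal in every mapped channel.

Only attribution in the removal report depends on the rule order; the
surviving set does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROTEIN_ID_COL = "Protein IDs"
GENE_NAME_COL = "Gene names"
REVERSE_COL = "Reverse"
CONTAMINANT_COL = "Potential contaminant"
SITE_ONLY_COL = "Only identified by site"
UNIQUE_PEPTIDES_COL = "Unique peptides"
REPORTER_PREFIX = "Reporter intensity corrected"

CONDITIONS = ("treated", "untreated")
ROLES = ("test", "control", "temperature")


class SchemaError(ValueError):
    """The input table does not match the expected proteinGroups dialect."""


class DesignError(ValueError):
    """Channel metadata is inconsistent with the requested experiment layout."""


@dataclass(frozen=True)
class ChannelMeta:
    """Metadata for one TMT reporter channel.

    ``role`` is ``"test"`` (ramped/heated sample) or ``"control"`` (37 C
    hold) for single-tube layouts, or ``"temperature"`` for TPP layouts where
    ``temperature`` carries the ladder point in degrees C.
    """

    name: str
    condition: str
    replicate: int
    role: str
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DesignError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.role not in ROLES:
            raise DesignError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "temperature" and self.temperature is None:
            raise DesignError(f"channel {self.name!r}: temperature role requires a temperature")


@dataclass
class IntensityMatrix:
    """Proteins x channels reporter intensities plus QC annotations.

    ``scale`` is ``"raw"`` for non-negative reporter intensities and
    ``"glog2"`` after variance stabilization (values may then be negative).
    """

    protein_ids: np.ndarray
    gene_names: np.ndarray
    reverse: np.ndarray
    contaminant: np.ndarray
    site_only: np.ndarray
    unique_peptides: np.ndarray
    intensities: np.ndarray
    channels: tuple[ChannelMeta, ...]
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.reverse = np.asarray(self.reverse, dtype=bool)
        self.contaminant = np.asarray(self.contaminant, dtype=bool)
        self.site_only = np.asarray(self.site_only, dtype=bool)
        self.unique_peptides = np.asarray(self.unique_peptides, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.channels = tuple(self.channels)
        n = self.protein_ids.shape[0]
        for arr_name in ("gene_names", "reverse", "contaminant", "site_only", "unique_peptides"):
            if getattr(self, arr_name).shape[0] != n:
                raise SchemaError(f"{arr_name} length does not match protein_ids")
        if self.intensities.shape != (n, len(self.channels)):
            raise SchemaError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{n} proteins x {len(self.channels)} channels"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise SchemaError("channel names must be unique")
        if self.scale == "raw" and self.intensities.size and np.nanmin(self.intensities) < 0:
            raise SchemaError("raw intensities must be non-negative")

    @property
    def n_proteins(self) -> int:
        return self.protein_ids.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_indices(self, condition: str | None = None, role: str | None = None,
                        replicate: int | None = None,
                        temperature: float | None = None) -> list[int]:
        """Indices of channels matching every given criterion."""
        out = []
        for i, ch in enumerate(self.channels):
            if condition is not None and ch.condition != condition:
                continue
            if role is not None and ch.role != role:
                continue
            if replicate is not None and ch.replicate != replicate:
                continue
            if temperature is not None and (
                ch.temperature is None or abs(ch.temperature - temperature) > 1e-9
            ):
                continue
            out.append(i)
        return out

    def subset(self, rows: np.ndarray) -> "IntensityMatrix":
        return IntensityMatrix(
            self.protein_ids[rows], self.gene_names[rows], self.reverse[rows],
            self.contaminant[rows], self.site_only[rows], self.unique_peptides[rows],
            self.intensities[rows], self.channels, self.scale,
        )

    def with_intensities(self, values: np.ndarray, scale: str | None = None) -> "IntensityMatrix":
        return IntensityMatrix(
            self.protein_ids, self.gene_names, self.reverse, self.contaminant,
            self.site_only, self.unique_peptides, values, self.channels,
            self.scale if scale is None else scale,
        )

    def to_frame(self) -> pd.DataFrame:
        """Render as a proteinGroups-dialect DataFrame ('+' flag convention)."""
        data = {
            PROTEIN_ID_COL: self.protein_ids,
            GENE_NAME_COL: self.gene_names,
            REVERSE_COL: np.where(self.reverse, "+", ""),
            CONTAMINANT_COL: np.where(self.contaminant, "+", ""),
            SITE_ONLY_COL: np.where(self.site_only, "+", ""),
            UNIQUE_PEPTIDES_COL: self.unique_peptides,
        }
        for j, ch in enumerate(self.channels):
            data[ch.name] = self.intensities[:, j]
        return pd.DataFrame(data)


def _parse_flag(series: pd.Series) -> np.ndarray:
    return series.fillna("").astype(str).str.strip().eq("+").to_numpy()


def read_protein_groups(path, channel_map: Iterable[ChannelMeta] | Mapping[str, Mapping]) -> IntensityMatrix:
    """Parse a proteinGroups-dialect TSV restricted to the mapped channels.

    ``channel_map`` assigns every reporter column in the file to its
    (condition, replicate, role[, temperature]); it may be a sequence of
    :class:`ChannelMeta` or a name-keyed mapping of field dicts.  A reporter
    column present in the file but absent from the map, or vice versa, is a
    :class:`SchemaError`.  Missing flag columns are treated as all-false with
    a logged warning; '+' parses to true.
    """
    channels = channel_map_from(channel_map)
    df = pd.read_csv(path, sep="\t", dtype={PROTEIN_ID_COL: str, GENE_NAME_COL: str},
                     float_precision="round_trip")

    mapped = {c.name for c in channels}
    in_file = [c for c in df.columns if c.startswith(REPORTER_PREFIX)]
    missing = sorted(mapped - set(in_file))
    if missing:
        raise SchemaError(f"reporter columns missing from file: {missing}")
    unmapped = sorted(set(in_file) - mapped)
    if unmapped:
        raise SchemaError(f"reporter columns present in file but not in channel map: {unmapped}")
    if PROTEIN_ID_COL not in df.columns:
        raise SchemaError(f"required column {PROTEIN_ID_COL!r} missing")

    flags = {}
    for col in (REVERSE_COL, CONTAMINANT_COL, SITE_ONLY_COL):
        if col in df.columns:
            flags[col] = _parse_flag(df[col])
        else:
            logger.warning("flag column %r missing; treating as all-false", col)
            flags[col] = np.zeros(len(df), dtype=bool)
    if UNIQUE_PEPTIDES_COL in df.columns:
        peptides = df[UNIQUE_PEPTIDES_COL].fillna(0).astype(int).to_numpy()
    else:
        logger.warning("column %r missing; treating as 0", UNIQUE_PEPTIDES_COL)
        peptides = np.zeros(len(df), dtype=int)
    genes = (df[GENE_NAME_COL] if GENE_NAME_COL in df.columns else df[PROTEIN_ID_COL]).fillna("")

    intensities = df[[c.name for c in channels]].fillna(0.0).to_numpy(dtype=float)
    return IntensityMatrix(
        protein_ids=df[PROTEIN_ID_COL].to_numpy(dtype=object),
        gene_names=genes.to_numpy(dtype=object),
        reverse=flags[REVERSE_COL],
        contaminant=flags[CONTAMINANT_COL],
        site_only=flags[SITE_ONLY_COL],
        unique_peptides=peptides,
        intensities=intensities,
        channels=tuple(channels),
    )


def channel_map_from(channel_map: Iterable[ChannelMeta] | Mapping[str, Mapping]) -> tuple[ChannelMeta, ...]:
    """Normalize a channel map (sequence of ChannelMeta or name-keyed dicts)."""
    if isinstance(channel_map, Mapping):
        metas = []
        for name, fields in channel_map.items():
            metas.append(ChannelMeta(
                name=name,
                condition=fields["condition"],
                replicate=int(fields["replicate"]),
                role=fields["role"],
                temperature=(float(fields["temperature"]) if fields.get("temperature") is not None else None),
            ))
        return tuple(metas)
    return tuple(channel_map)


@dataclass(frozen=True)
class FilterReport:
    """Per-rule removal counts, attributing each row to the first rule that
    removes it (flags, then peptide count, then channel completeness)."""

    input_rows: int
    flags: int
    peptides: int
    completeness: int
    survivors: int

    def as_dict(self) -> dict:
        return {
            "input_rows": self.input_rows, "flags": self.flags,
            "peptides": self.peptides, "completeness": self.completeness,
            "survivors": self.survivors,
        }


def apply_qc_filters(
    matrix: IntensityMatrix,
    min_unique_peptides: int = 2,
    require_complete: bool = True,
) -> tuple[IntensityMatrix, FilterReport]:
    """Apply the QC cascade and report per-rule removal counts.

    Removes flagged rows (reverse / contaminant / site-only), rows with
    fewer than ``min_unique_peptides`` unique peptides, and — when
    ``require_complete`` — rows lacking a strictly positive intensity in
    every mapped channel.  Idempotent; an empty result is allowed (with a
    warning), never an error.
    """
    flagged = matrix.reverse | matrix.contaminant | matrix.site_only
    few_peptides = matrix.unique_peptides < min_unique_peptides
    if require_complete:
        incomplete = ~np.all(matrix.intensities > 0, axis=1)
    else:
        incomplete = np.zeros(matrix.n_proteins, dtype=bool)

    removed_by_flags = flagged
    removed_by_peptides = few_peptides & ~flagged
    removed_by_completeness = incomplete & ~flagged & ~few_peptides
    keep = ~(flagged | few_peptides | incomplete)

    report = FilterReport(
        input_rows=matrix.n_proteins,
        flags=int(removed_by_flags.sum()),
        peptides=int(removed_by_peptides.sum()),
        completeness=int(removed_by_completeness.sum()),
        survivors=int(keep.sum()),
    )
    if report.survivors == 0:
        logger.warning("QC filtering removed every protein")
    return matrix.subset(keep), report
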