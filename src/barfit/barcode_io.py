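"""Barcode library / sample sheet containers, exact-match FASTQ counting,
the low-count filter, and barcode cross-contamination rates.

A read is counted toward a (sample, barcode) cell only if its forward index,
both layout anchors, the 20 bp barcode and the reverse index all match the
declared layout exactly; everything else is tallied as discarded.  Entries at
or below the low-count threshold (default 20 reads) become missing (NA) and
stay missing through every downstream computation.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .layout import DEFAULT_LAYOUT, ReadLayout

logger = logging.getLogger("barfit")

BARCODE_ALPHABET = frozenset("ACGT")

#: canonical column order for count tables
COUNT_COLUMNS = ["sample_id", "barcode", "reads"]

SHEET_COLUMNS = [
    "sample_id",
    "fwd_index",
    "rev_index",
    "day",
    "chemical",
    "stress_fraction",
    "timepoint_h",
    "replicate",
    "pool_id",
    "sentinel",
    "expected_barcodes",
]


class LibraryError(ValueError):
    pass


class SampleSheetError(ValueError):
    pass


@dataclass(frozen=True)
class BarcodeLibrary:
    """The barcode table: id -> 20 bp sequence, with one flagged reference.

    The reference strain (``d1H10`` in the study layout) is spiked into every
    competition pool and anchors all relative fitness values.
    """

    sequences: Mapping[str, str]
    reference_id: str = "d1H10"

    def __post_init__(self) -> None:
        if self.reference_id not in self.sequences:
            raise LibraryError(f"reference id {self.reference_id!r} not in library")
        seen: dict[str, str] = {}
        for bc_id, seq in self.sequences.items():
            if len(seq) != 20:
                raise LibraryError(f"{bc_id}: barcode must be 20 bp, got {len(seq)}")
            if set(seq) - BARCODE_ALPHABET:
                raise LibraryError(f"{bc_id}: barcode has non-ACGT characters")
            if seq in seen:
                raise LibraryError(f"duplicate barcode sequence for {bc_id} and {seen[seq]}")
            seen[seq] = bc_id

    @property
    def barcode_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def nonreference_ids(self) -> list[str]:
        return [b for b in self.sequences if b != self.reference_id]

    def sequence_to_id(self) -> dict[str, str]:
        return {seq: bc_id for bc_id, seq in self.sequences.items()}

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "barcode": list(self.sequences),
                "sequence": list(self.sequences.values()),
                "is_reference": [b == self.reference_id for b in self.sequences],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BarcodeLibrary":
        df = pd.read_csv(path, sep="\t", comment="#")
        refs = df.loc[df["is_reference"].astype(bool), "barcode"]
        if len(refs) != 1:
            raise LibraryError(f"library must flag exactly one reference, found {len(refs)}")
        return cls(
            sequences=dict(zip(df["barcode"], df["sequence"])),
            reference_id=str(refs.iloc[0]),
        )


@dataclass
class SampleSheet:
    """Sample metadata: index pair, day, assay environment, replicate, pool,
    and (for sentinel wells) the expected barcode set.

    ``expected_barcodes`` is a semicolon-joined id list; the empty string means
    "every pool barcode" (non-sentinel competition samples).
    """

    df: pd.DataFrame
    layout: ReadLayout = field(default_factory=lambda: DEFAULT_LAYOUT)

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.df.columns]
        if missing:
            raise SampleSheetError(f"sample sheet missing columns: {missing}")
        df = self.df
        if df["sample_id"].duplicated().any():
            raise SampleSheetError("duplicate sample ids")
        pairs = list(zip(df["fwd_index"], df["rev_index"]))
        if len(set(pairs)) != len(pairs):
            raise SampleSheetError("index pairs must be unique across samples")
        for col in ("fwd_index", "rev_index"):
            lengths = df[col].astype(str).str.len()
            bad = ~lengths.between(self.layout.min_index_length, self.layout.max_index_length)
            if bad.any():
                raise SampleSheetError(
                    f"{col}: index lengths outside "
                    f"[{self.layout.min_index_length}, {self.layout.max_index_length}]"
                )
        if not df["day"].isin([0, 50]).all():
            raise SampleSheetError("day must be 0 or 50")
        if not df["timepoint_h"].isin([0, 48]).all():
            raise SampleSheetError("timepoint_h must be 0 or 48")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def sentinel_samples(self) -> pd.DataFrame:
        return self.df[self.df["sentinel"].astype(bool)]

    def expected_set(self, sample_id: str, library: BarcodeLibrary) -> set[str]:
        row = self.df.loc[self.df["sample_id"] == sample_id]
        if row.empty:
            raise SampleSheetError(f"unknown sample {sample_id!r}")
        raw = str(row["expected_barcodes"].iloc[0] or "")
        if raw in ("", "nan"):
            return set(library.barcode_ids)
        return set(raw.split(";"))

    def to_tsv(self, path) -> None:
        self.df[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, layout: ReadLayout = DEFAULT_LAYOUT) -> "SampleSheet":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={"expected_barcodes": str},
            keep_default_na=False,
            na_values=[],
        )
        df["day"] = df["day"].astype(int)
        df["timepoint_h"] = df["timepoint_h"].astype(int)
        df["stress_fraction"] = df["stress_fraction"].astype(float)
        df["sentinel"] = df["sentinel"].astype(str).str.lower().isin(["true", "1"])
        return cls(df=df, layout=layout)


# --------------------------------------------------------------------- parsing


@dataclass
class ParseSummary:
    """Read accounting for one parse: retained + discarded = total, always."""

    total: int = 0
    retained: int = 0
    discarded_by_category: dict = field(default_factory=dict)
    reference_reads: int = 0

    @property
    def discarded(self) -> int:
        return sum(self.discarded_by_category.values())

    @property
    def nonreference_reads(self) -> int:
        return self.retained - self.reference_reads

    @property
    def nonreference_percentage(self) -> float:
        return nonreference_percentage(self.nonreference_reads, self.retained)


def nonreference_percentage(nonreference_reads: int, retained_reads: int) -> float:
    """Percent of retained reads mapping to non-reference barcodes."""
    if retained_reads <= 0:
        return float("nan")
    return 100.0 * nonreference_reads / retained_reads


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_reads(
    fastq_paths,
    sheet: SampleSheet,
    library: BarcodeLibrary,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> tuple[pd.DataFrame, ParseSummary]:
    """Demultiplex FASTQ reads into a raw count table under the exact-match rule.

    A read increments (sample, barcode) iff the forward index, both anchors,
    the 20-mer and the reverse index match the declared layout perfectly.
    Reads whose index pair matches a sample but whose 20-mer is absent from the
    library are discarded (category ``unknown_barcode``), not treated as
    contamination.

    Returns the raw long-format count table (one row per sample x library
    barcode, zeros included) and a :class:`ParseSummary`.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]

    a1, a2 = layout.anchor1, layout.anchor2
    la1, la2 = len(a1), len(a2)
    bl = layout.barcode_length

    fwd_lengths = sorted({len(str(f)) for f in sheet.df["fwd_index"]})
    pair_to_sample = {
        (str(r.fwd_index), str(r.rev_index)): r.sample_id
        for r in sheet.df.itertuples()
    }
    fwd_by_len: dict[int, set[str]] = {}
    for f, _ in pair_to_sample:
        fwd_by_len.setdefault(len(f), set()).add(f)

    seq_to_id = library.sequence_to_id()
    ref_id = library.reference_id

    counts: dict[tuple[str, str], int] = {}
    summary = ParseSummary()
    cats = summary.discarded_by_category
    cats.setdefault("unmatched_layout", 0)
    cats.setdefault("unknown_barcode", 0)

    for path in fastq_paths:
        with _open_maybe_gzip(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                summary.total += 1
                seq = seq.upper()
                matched = False
                for flen in fwd_lengths:
                    if seq[:flen] not in fwd_by_len.get(flen, ()):
                        continue
                    if seq[flen : flen + la1] != a1:
                        continue
                    bc_end = flen + la1 + bl
                    if seq[bc_end : bc_end + la2] != a2:
                        continue
                    rev = seq[bc_end + la2 :]
                    sample = pair_to_sample.get((seq[:flen], rev))
                    if sample is None:
                        continue
                    barcode = seq_to_id.get(seq[flen + la1 : bc_end])
                    if barcode is None:
                        cats["unknown_barcode"] += 1
                    else:
                        counts[(sample, barcode)] = counts.get((sample, barcode), 0) + 1
                        summary.retained += 1
                        if barcode == ref_id:
                            summary.reference_reads += 1
                    matched = True
                    break
                if not matched:
                    cats["unmatched_layout"] += 1

    rows = [
        (sample, barcode, counts.get((sample, barcode), 0))
        for sample in sheet.sample_ids
        for barcode in library.barcode_ids
    ]
    table = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return table, summary


# -------------------------------------------------------------------- filtering


def low_count_filter(table: pd.DataFrame, threshold: int = 20) -> pd.DataFrame:
    """Mark entries with ``reads <= threshold`` as missing (NA).

    Low counts are dominated by sampling noise, so they are removed rather
    than propagated into log-ratio fitness estimates.  Idempotent: missing
    entries stay missing.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    out = table.copy()
    reads = out["reads"].astype(float)
    out["reads"] = reads.mask(reads <= threshold)
    return out


def counts_to_tsv(table: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA")


def counts_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    return df


# ----------------------------------------------------------------- contamination


@dataclass
class ContaminationReport:
    """Cross-contamination rates from sentinel wells.

    per_sample: one percentage per usable sentinel sample.
    per_set / overall: mean +/- s.d. summaries.
    """

    per_sample: pd.DataFrame
    per_set: pd.DataFrame
    overall_mean: float
    overall_sd: float
    excluded: list[str] = field(default_factory=list)


def contamination_rate(
    table: pd.DataFrame,
    sheet: SampleSheet,
    library: BarcodeLibrary,
) -> ContaminationReport:
    """Barcode cross-contamination: reads on library barcodes *not expected*
    in a sentinel sample, as a percentage of that sample's library reads.

    Sentinel wells are seeded with a known barcode pair, so any other library
    barcode observed there arrived by cross-contamination.  Samples with zero
    total reads are excluded (rate undefined) and logged.
    """
    sentinels = sheet.sentinel_samples()
    rows = []
    excluded: list[str] = []
    for r in sentinels.itertuples():
        expected = sheet.expected_set(r.sample_id, library)
        if not expected:
            raise ValueError(f"sentinel {r.sample_id} has an empty expected set")
        sub = table[table["sample_id"] == r.sample_id]
        reads = sub["reads"].astype(float)
        total = float(np.nansum(reads))
        if total <= 0:
            logger.warning("sentinel %s has zero reads; contamination undefined", r.sample_id)
            excluded.append(r.sample_id)
            continue
        unexpected = float(np.nansum(reads[~sub["barcode"].isin(expected)]))
        set_label = "Day-0" if r.day == 0 else f"Day-50 {r.chemical}"
        rows.append((r.sample_id, set_label, 100.0 * unexpected / total))

    per_sample = pd.DataFrame(rows, columns=["sample_id", "set", "contamination_pct"])
    if per_sample.empty:
        per_set = pd.DataFrame(columns=["set", "mean_pct", "sd_pct", "n"])
        return ContaminationReport(per_sample, per_set, float("nan"), float("nan"), excluded)
    per_set = (
        per_sample.groupby("set")["contamination_pct"]
        .agg(mean_pct="mean", sd_pct="std", n="size")
        .reset_index()
    )
    return ContaminationReport(
        per_sample=per_sample,
        per_set=per_set,
        overall_mean=float(per_sample["contamination_pct"].mean()),
        overall_sd=float(per_sample["contamination_pct"].std()),
        excluded=excluded,
    )
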