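"""Raw two-channel intensity tables: container, TSV round-trip, QC-flag filter.

The on-disk dialect mirrors an Agilent-Feature-Extraction-like export
flattened to one row per probe: four annotation columns, a spike-in status
column, then per sample a ``<sample>_Cy5_raw`` (IP channel), ``<sample>_Cy3_raw``
(supernatant channel) and ``<sample>_Flag`` column.  A separate two-column
sample sheet maps each sample to its group (e.g. proliferative vs involuting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lncRNA", "pri-miRNA", "pre-miRNA", "snoRNA", "snRNA")
SPIKEIN_STATES = ("pos", "neg", "none")
FLAG_STATES = ("P", "M", "A")
PRESENT_FLAGS = frozenset({"P", "M"})

ANNOTATION_COLUMNS = ("ProbeName", "TranscriptID", "GeneSymbol", "RNAClass", "SpikeIn")

CY5 = "cy5"  # IP channel (methylated fraction)
CY3 = "cy3"  # supernatant channel (unmethylated fraction)
CHANNELS = (CY5, CY3)


@dataclass
class RawArraySet:
    """Probe x sample raw two-channel intensities with QC flags.

    Attributes
    ----------
    probes : DataFrame indexed by probe_id with columns
        ``transcript_id, gene_symbol, rna_class, spikein``.
    samples : DataFrame indexed by sample_id with column ``group``;
        groups must partition the samples into exactly two non-empty sets.
    cy5, cy3 : float DataFrames (probe x sample); NaN marks a missing
        (nonpositive or unparseable) intensity.
    flags : str DataFrame (probe x sample) with values P/M/A.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    cy5: pd.DataFrame
    cy3: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        if not self.probes.index.is_unique:
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise ConsistencyError(f"duplicate probe_id {dup!r}")
        bad_class = set(self.probes["rna_class"]) - set(RNA_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown rna_class values: {sorted(bad_class)}")
        bad_spike = set(self.probes["spikein"]) - set(SPIKEIN_STATES)
        if bad_spike:
            raise ValidationError(f"unknown spikein values: {sorted(bad_spike)}")
        groups = self.samples["group"]
        if groups.nunique() != 2 or groups.value_counts().min() < 1:
            raise ConsistencyError(
                "sample groups must partition samples into exactly two non-empty sets; "
                f"got {groups.value_counts().to_dict()}"
            )
        for name, frame in (("cy5", self.cy5), ("cy3", self.cy3), ("flags", self.flags)):
            if not frame.index.equals(self.probes.index):
                raise ConsistencyError(f"{name} rows do not match the probe index")
            if list(frame.columns) != list(self.samples.index):
                raise ConsistencyError(f"{name} columns do not match the sample sheet")
        bad_flags = set(np.unique(self.flags.to_numpy())) - set(FLAG_STATES)
        if bad_flags:
            raise ValidationError(f"unknown QC flags: {sorted(bad_flags)}")

    # -- conveniences ------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def group_names(self) -> tuple[str, str]:
        """The two group labels in sample-sheet order of first appearance."""
        seen = list(dict.fromkeys(self.samples["group"]))
        return seen[0], seen[1]

    def channel(self, channel: str) -> pd.DataFrame:
        if channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}, got {channel!r}")
        return self.cy5 if channel == CY5 else self.cy3

    def subset_probes(self, probe_ids: pd.Index) -> "RawArraySet":
        return RawArraySet(
            probes=self.probes.loc[probe_ids],
            samples=self.samples,
            cy5=self.cy5.loc[probe_ids],
            cy3=self.cy3.loc[probe_ids],
            flags=self.flags.loc[probe_ids],
        )

    def equals(self, other: "RawArraySet") -> bool:
        return (
            self.probes.equals(other.probes)
            and self.samples.equals(other.samples)
            and self.cy5.equals(other.cy5)
            and self.cy3.equals(other.cy3)
            and self.flags.equals(other.flags)
        )


# ---------------------------------------------------------------------------
# TSV writer / reader
# ---------------------------------------------------------------------------

def write_raw_table(raw: RawArraySet, path) -> None:
    """Write a RawArraySet as a single tab-delimited table.

    Missing intensities are emitted as 0 so that the round-trip through the
    nonpositive-becomes-missing rule is the identity.
    """
    out = pd.DataFrame(
        {
            "ProbeName": raw.probes.index,
            "TranscriptID": raw.probes["transcript_id"].to_numpy(),
            "GeneSymbol": raw.probes["gene_symbol"].to_numpy(),
            "RNAClass": raw.probes["rna_class"].to_numpy(),
            "SpikeIn": raw.probes["spikein"].to_numpy(),
        }
    )
    for s in raw.sample_ids:
        out[f"{s}_Cy5_raw"] = raw.cy5[s].fillna(0.0).to_numpy()
        out[f"{s}_Cy3_raw"] = raw.cy3[s].fillna(0.0).to_numpy()
        out[f"{s}_Flag"] = raw.flags[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_sample_sheet(raw: RawArraySet, path) -> None:
    sheet = raw.samples.reset_index()
    sheet.columns = ["sample_id", "group"]
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise FormatError(f"sample sheet is missing mandatory column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise ConsistencyError("sample sheet contains duplicate sample_id entries")
    return sheet.set_index("sample_id")


def read_raw_table(path, sample_sheet_path, column_map: dict | None = None) -> RawArraySet:
    """Read a raw intensity TSV plus sample sheet into a validated RawArraySet.

    Parameters
    ----------
    column_map : optional mapping of vendor column names to the canonical
        dialect (e.g. ``{"SystematicName": "TranscriptID"}``), applied to the
        header before parsing.

    Nonpositive or unparseable intensities become missing (NaN); the count of
    such cells is logged.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        table = table.rename(columns=column_map)
    for col in ANNOTATION_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"raw table is missing mandatory column {col!r}")

    samples = read_sample_sheet(sample_sheet_path)
    for s in samples.index:
        for suffix in ("Cy5_raw", "Cy3_raw", "Flag"):
            if f"{s}_{suffix}" not in table.columns:
                raise ConsistencyError(
                    f"sample {s!r} from the sample sheet has no {suffix} column in the table"
                )

    probes = pd.DataFrame(
        {
            "transcript_id": table["TranscriptID"].to_numpy(),
            "gene_symbol": table["GeneSymbol"].to_numpy(),
            "rna_class": table["RNAClass"].to_numpy(),
            "spikein": table["SpikeIn"].to_numpy(),
        },
        index=pd.Index(table["ProbeName"], name="probe_id"),
    )

    def to_float(series: pd.Series) -> np.ndarray:
        # numpy's parser round-trips float64 text exactly; fall back per
        # element only when the column holds unparseable tokens
        try:
            return series.to_numpy(dtype=float)
        except (TypeError, ValueError):
            def conv(x):
                try:
                    return float(x)
                except (TypeError, ValueError):
                    return np.nan
            return np.array([conv(x) for x in series], dtype=float)

    def parse_channel(suffix: str) -> pd.DataFrame:
        cols = {}
        n_missing = 0
        for s in samples.index:
            vals = pd.Series(to_float(table[f"{s}_{suffix}"]), index=table.index)
            vals = vals.where(vals > 0)  # nonpositive -> missing
            n_missing += int(vals.isna().sum())
            cols[s] = vals.to_numpy(dtype=float)
        frame = pd.DataFrame(cols, index=probes.index)
        if n_missing:
            logger.info("%d nonpositive/unparseable %s intensities set to missing", n_missing, suffix)
        return frame

    cy5 = parse_channel("Cy5_raw")
    cy3 = parse_channel("Cy3_raw")
    flags = pd.DataFrame(
        {s: table[f"{s}_Flag"].to_numpy() for s in samples.index}, index=probes.index
    )
    return RawArraySet(probes=probes, samples=samples, cy5=cy5, cy3=cy3, flags=flags)


# ---------------------------------------------------------------------------
# QC-flag probe filter
# ---------------------------------------------------------------------------

def filter_by_flags(raw: RawArraySet, min_present: int = 3) -> RawArraySet:
    """Retain probes flagged Present or Marginal in at least ``min_present`` samples.

    Spike-in probes are always retained: they anchor the per-sample
    normalization and must survive QC filtering.  Idempotent; intensities
    are never altered, only the probe set shrinks.
    """
    n_samples = len(raw.sample_ids)
    if min_present > n_samples:
        raise ValidationError(
            f"min_present={min_present} exceeds the number of samples ({n_samples})"
        )
    present = raw.flags.isin(PRESENT_FLAGS).sum(axis=1)
    keep = (present >= min_present) | (raw.probes["spikein"] != "none")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("flag filter dropped %d of %d probes", dropped, len(keep))
    return raw.subset_probes(raw.probes.index[keep])
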