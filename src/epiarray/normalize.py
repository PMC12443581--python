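"""Spike-in log2 normalization; per-transcript m6A quantity and expression level.

For every sample and channel the normalization anchor is the arithmetic mean
of log2 spike-in raw intensities (equivalently the log2 geometric mean), and

    normalized = log2(raw) - mean(log2(spike-in raws))

The per-transcript methylation statistic ("m6A quantity") is the normalized
IP/Cy5 intensity; the abundance statistic ("gene expression level") is the
sum of the normalized IP/Cy5 and supernatant/Cy3 intensities.  Both are in
log2 units and invariant to per-sample, per-channel multiplicative rescaling
of the raw intensities (spike-ins included).

Multiple probes per transcript are collapsed to one value by the median of
normalized values (even count: mean of the central pair), after normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrayio import CY3, CY5, RawArraySet
from .errors import NormalizationError, ValidationError

logger = logging.getLogger(__name__)

SPIKE_POLICIES = ("all", "matched")


@dataclass
class NormalizedProfile:
    """Per-transcript, per-sample normalized statistics (log2 units).

    Attributes
    ----------
    transcripts : DataFrame indexed by transcript_id with columns
        ``rna_class, gene_symbol`` (spike-in probes are excluded).
    samples : DataFrame indexed by sample_id with column ``group``.
    m6a : DataFrame (transcript x sample), the m6A quantity
        (= normalized IP/Cy5 intensity, probe-collapsed).
    expression : DataFrame (transcript x sample), the gene expression level
        (= normalized IP + normalized Sup, probe-collapsed); NaN where either
        channel is missing.
    spikein_log2_means : DataFrame (sample x channel) of normalization anchors.
    """

    transcripts: pd.DataFrame
    samples: pd.DataFrame
    m6a: pd.DataFrame
    expression: pd.DataFrame
    spikein_log2_means: pd.DataFrame

    @property
    def group_names(self) -> tuple[str, str]:
        seen = list(dict.fromkeys(self.samples["group"]))
        return seen[0], seen[1]

    def measure(self, name: str) -> pd.DataFrame:
        if name == "m6a":
            return self.m6a
        if name == "expression":
            return self.expression
        raise ValidationError(f"measure must be 'm6a' or 'expression', got {name!r}")


def _spike_mask(raw: RawArraySet, channel: str, policy: str) -> pd.Series:
    if policy not in SPIKE_POLICIES:
        raise ValidationError(f"spike-in policy must be one of {SPIKE_POLICIES}")
    if policy == "all":
        return raw.probes["spikein"] != "none"
    wanted = "pos" if channel == CY5 else "neg"
    return raw.probes["spikein"] == wanted


def spikein_log2_mean(
    raw: RawArraySet, sample: str, channel: str, policy: str = "all"
) -> float:
    """Arithmetic mean of log2 spike-in raw intensities for one sample/channel.

    Under the default ``all`` policy every spike-in probe with a positive raw
    value in the channel contributes; ``matched`` restricts to positive
    spike-ins for Cy5 and negative ones for Cy3.
    """
    if sample not in raw.sample_ids:
        raise ValidationError(f"unknown sample {sample!r}")
    vals = raw.channel(channel).loc[_spike_mask(raw, channel, policy), sample].dropna()
    if vals.empty:
        raise NormalizationError(
            f"no usable spike-in intensity for sample {sample!r} channel {channel!r}"
        )
    return float(np.log2(vals.to_numpy()).mean())


def normalize_channel(
    raw: RawArraySet, channel: str, policy: str = "all"
) -> pd.DataFrame:
    """Per-probe, per-sample log2 spike-in-normalized intensities.

    Samples with no usable spike-in in the channel are dropped with a warning.
    Missing raws stay missing.
    """
    anchors = {}
    for s in raw.sample_ids:
        try:
            anchors[s] = spikein_log2_mean(raw, s, channel, policy)
        except NormalizationError:
            logger.warning(
                "sample %r excluded: no usable spike-in in channel %r", s, channel
            )
    if not anchors:
        raise NormalizationError(f"no sample has usable spike-ins in channel {channel!r}")
    values = raw.channel(channel)[list(anchors)]
    return np.log2(values) - pd.Series(anchors)


def _collapse_probes(values: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    """Median-collapse probe-level values to transcript level (spike-ins dropped)."""
    keep = probes["spikein"] == "none"
    grouped = values.loc[keep].groupby(probes.loc[keep, "transcript_id"], sort=True)
    return grouped.median()


def build_profile(raw: RawArraySet, policy: str = "all") -> NormalizedProfile:
    """Normalize both channels and assemble the transcript-level profile.

    Only samples normalizable in *both* channels are retained.  The m6A
    quantity is defined wherever the IP channel is; the expression level
    requires both channels at the probe level and is NaN (with a logged
    count) elsewhere.
    """
    ip = normalize_channel(raw, CY5, policy)
    sup = normalize_channel(raw, CY3, policy)
    common = [s for s in raw.sample_ids if s in ip.columns and s in sup.columns]
    if not common:
        raise NormalizationError("no sample is normalizable in both channels")
    ip, sup = ip[common], sup[common]

    expr_probe = ip + sup  # NaN wherever either channel is missing
    n_half_missing = int((expr_probe.isna() & ~(ip.isna() & sup.isna())).sum().sum())
    if n_half_missing:
        logger.info(
            "%d probe-sample cells missing one channel: expression level undefined there",
            n_half_missing,
        )

    m6a = _collapse_probes(ip, raw.probes)
    expression = _collapse_probes(expr_probe, raw.probes)

    keep = raw.probes["spikein"] == "none"
    transcripts = (
        raw.probes.loc[keep, ["transcript_id", "rna_class", "gene_symbol"]]
        .drop_duplicates("transcript_id")
        .set_index("transcript_id")
        .loc[m6a.index]
    )
    anchors = pd.DataFrame(
        {
            CY5: [spikein_log2_mean(raw, s, CY5, policy) for s in common],
            CY3: [spikein_log2_mean(raw, s, CY3, policy) for s in common],
        },
        index=pd.Index(common, name="sample_id"),
    )
    return NormalizedProfile(
        transcripts=transcripts,
        samples=raw.samples.loc[common],
        m6a=m6a,
        expression=expression,
        spikein_log2_means=anchors,
    )


def m6a_quantity(profile: NormalizedProfile) -> pd.DataFrame:
    """The per-transcript methylation statistic (normalized IP intensity)."""
    return profile.m6a


def expression_level(profile: NormalizedProfile) -> pd.DataFrame:
    """The per-transcript abundance statistic (normalized IP + Sup)."""
    return profile.expression


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_profile(profile: NormalizedProfile, path) -> None:
    out = profile.transcripts.copy()
    for s in profile.samples.index:
        out[f"{s}_m6a"] = profile.m6a[s]
        out[f"{s}_expr"] = profile.expression[s]
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_profile(path, sample_sheet) -> NormalizedProfile:
    """Read a profile TSV written by :func:`write_profile`.

    ``sample_sheet`` is a DataFrame indexed by sample_id with a ``group``
    column (see :func:`epiarray.arrayio.read_sample_sheet`); spike-in anchors
    are not stored in the TSV and come back empty.
    """
    table = pd.read_csv(path, sep="\t", index_col="transcript_id")
    samples = [s for s in sample_sheet.index if f"{s}_m6a" in table.columns]
    if not samples:
        raise ValidationError("no sample sheet entry matches the profile columns")
    m6a = table[[f"{s}_m6a" for s in samples]].set_axis(samples, axis=1)
    expr = table[[f"{s}_expr" for s in samples]].set_axis(samples, axis=1)
    return NormalizedProfile(
        transcripts=table[["rna_class", "gene_symbol"]],
        samples=sample_sheet.loc[samples],
        m6a=m6a,
        expression=expr,
        spikein_log2_means=pd.DataFrame(columns=[CY5, CY3]),
    )
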