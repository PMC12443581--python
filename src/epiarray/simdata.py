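"""Synthetic two-channel MeRIP-array datasets (and qPCR plates) with known truth.

Measurement model
-----------------
Each transcript *i* carries a latent log2 abundance ``E_i`` and a methylated
fraction ``m_i`` in (0, 1).  Antibody pull-down splits the transcript's
molecules between the two dye channels of one array: the IP (Cy5) channel
sees the methylated fraction and the supernatant (Cy3) channel the rest, so
for sample *s* in group *g*::

    E[IP raw]  = A * 2**E_ig * m_ig
    E[Sup raw] = A * 2**E_ig * (1 - m_ig)

each multiplied by independent lognormal noise ``2**N(0, noise_sd**2)``.
Planted differential methylation shifts ``m`` on the log-odds scale (keeping
it inside (0, 1)); planted differential expression shifts ``E`` on the log2
scale.  Effects are applied to group 2 relative to group 1, matching a
proliferative-to-involuting contrast where "up" means higher in group 2.

Spike-in probes emit a fixed raw level split by a fixed methylated fraction
(0.9 for positive controls, 0.0 for negative ones), noise-free, so the
per-sample spike-in log2 average is a stable normalization anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .arrayio import RNA_CLASSES, RawArraySet
from .errors import ValidationError

__all__ = ["SimConfig", "DEFAULT_CLASS_CENSUS", "simulate_dataset", "simulate_qpcr_plate"]

# Transcript census of the profiled human array, by RNA class.
DEFAULT_CLASS_CENSUS: dict[str, int] = {
    "mRNA": 41263,
    "lncRNA": 10492,
    "pri-miRNA": 1431,
    "pre-miRNA": 943,
    "snoRNA": 684,
    "snRNA": 19,
}

GROUP_NAMES = ("proliferative", "involuting")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for one synthetic two-group MeRIP-array experiment.

    Defaults emulate the profiled study design: 2 groups x 3 replicate
    arrays, the full ~55k-transcript class census, lognormal intensity noise
    of 0.25 on the log2 scale, and planted differential-methylation /
    expression fractions near the study's detected rates.
    """

    n_transcripts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CENSUS)
    )
    n_per_group: int = 3
    frac_dm_up: float = 0.015
    frac_dm_down: float = 0.02
    frac_de_up: float = 0.01
    frac_de_down: float = 0.02
    dm_effect: float = 2.0       # log-odds shift of the methylated fraction
    de_effect: float = 1.0       # log2 abundance shift
    couple_dm_de: bool = False   # planted DM transcripts also get a same-sign DE shift
    noise_sd: float = 0.25       # lognormal multiplicative noise SD, log2 scale
    n_spikein_pos: int = 8
    n_spikein_neg: int = 8
    spikein_level: float = 5000.0
    frac_absent_flags: float = 0.02
    probes_per_transcript: int = 1
    meth_beta_a: float = 2.0     # baseline methylated fraction ~ Beta(a, b)
    meth_beta_b: float = 5.0
    abundance_log2_mean: float = 13.0
    abundance_log2_sd: float = 1.5
    scale: float = 1.0           # global intensity scale A
    group_names: tuple[str, str] = GROUP_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dm_up", "frac_dm_down", "frac_de_up", "frac_de_down",
                     "frac_absent_flags"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} must lie in [0, 1]")
        if self.frac_dm_up + self.frac_dm_down > 1.0:
            raise ValidationError("frac_dm_up + frac_dm_down exceeds 1")
        if self.frac_de_up + self.frac_de_down > 1.0:
            raise ValidationError("frac_de_up + frac_de_down exceeds 1")
        if not self.n_transcripts or any(c < 1 for c in self.n_transcripts.values()):
            raise ValidationError("n_transcripts must map classes to counts >= 1")
        if set(self.n_transcripts) - set(RNA_CLASSES):
            raise ValidationError(
                f"unknown RNA classes: {sorted(set(self.n_transcripts) - set(RNA_CLASSES))}"
            )
        if self.n_per_group < 1 or self.probes_per_transcript < 1:
            raise ValidationError("n_per_group and probes_per_transcript must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.spikein_level <= 0 or self.scale <= 0:
            raise ValidationError("spikein_level and scale must be > 0")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def simulate_dataset(config: SimConfig) -> tuple[RawArraySet, pd.DataFrame]:
    """Generate one synthetic experiment.

    Returns
    -------
    raw : RawArraySet
        Probe-level two-channel raw intensities with QC flags and spike-ins.
    truth : DataFrame indexed by transcript_id
        Ground truth: rna_class, gene_symbol, per-group latent log2 abundance
        (``abundance_log2_g1/g2``) and methylated fraction (``meth_frac_g1/g2``),
        and the planted labels ``dm_label``/``de_label`` in {up, down, null}.

    Deterministic under a fixed config (including seed).
    """
    root = np.random.SeedSequence(config.seed)
    ss_truth, ss_noise, ss_flags = root.spawn(3)
    rng = np.random.default_rng(ss_truth)

    classes = [c for c in RNA_CLASSES if c in config.n_transcripts]
    rna_class = np.repeat(classes, [config.n_transcripts[c] for c in classes])
    n = rna_class.size
    transcript_id = np.array([f"TX{i:06d}" for i in range(n)])
    gene_symbol = np.array([f"GENE{i:06d}" for i in range(n)])

    # latent baselines
    abundance = rng.normal(config.abundance_log2_mean, config.abundance_log2_sd, n)
    meth = rng.beta(config.meth_beta_a, config.meth_beta_b, n)
    # keep strictly inside (0, 1)
    meth = np.clip(meth, 1e-6, 1.0 - 1e-6)

    # planted labels: a random permutation carves out DM up / DM down;
    # an independent permutation carves out DE, unless coupling is requested.
    dm_label = np.full(n, "null", dtype=object)
    de_label = np.full(n, "null", dtype=object)
    n_dm_up = int(round(config.frac_dm_up * n))
    n_dm_down = int(round(config.frac_dm_down * n))
    order = rng.permutation(n)
    dm_up_idx = order[:n_dm_up]
    dm_down_idx = order[n_dm_up:n_dm_up + n_dm_down]
    dm_label[dm_up_idx] = "up"
    dm_label[dm_down_idx] = "down"

    n_de_up = int(round(config.frac_de_up * n))
    n_de_down = int(round(config.frac_de_down * n))
    if config.couple_dm_de:
        de_up_idx = dm_up_idx[: min(n_de_up, dm_up_idx.size)]
        de_down_idx = dm_down_idx[: min(n_de_down, dm_down_idx.size)]
    else:
        order2 = rng.permutation(n)
        de_up_idx = order2[:n_de_up]
        de_down_idx = order2[n_de_up:n_de_up + n_de_down]
    de_label[de_up_idx] = "up"
    de_label[de_down_idx] = "down"

    dm_shift = np.where(dm_label == "up", config.dm_effect,
                        np.where(dm_label == "down", -config.dm_effect, 0.0))
    de_shift = np.where(de_label == "up", config.de_effect,
                        np.where(de_label == "down", -config.de_effect, 0.0))

    abundance_g = np.stack([abundance, abundance + de_shift])          # (2, n)
    meth_g = np.stack([meth, _logistic(_logit(meth) + dm_shift)])      # (2, n)

    truth = pd.DataFrame(
        {
            "rna_class": rna_class,
            "gene_symbol": gene_symbol,
            "abundance_log2_g1": abundance_g[0],
            "abundance_log2_g2": abundance_g[1],
            "meth_frac_g1": meth_g[0],
            "meth_frac_g2": meth_g[1],
            "dm_label": dm_label,
            "de_label": de_label,
        },
        index=pd.Index(transcript_id, name="transcript_id"),
    )

    # expand transcripts to probes
    k = config.probes_per_transcript
    probe_tx = np.repeat(np.arange(n), k)
    if k == 1:
        probe_names = np.char.add("P_", transcript_id)
    else:
        probe_names = np.array(
            [f"P_{transcript_id[t]}_{j}" for t in range(n) for j in range(k)]
        )

    samples = [f"{g}_{r + 1}" for g in config.group_names for r in range(config.n_per_group)]
    group_of = np.repeat([0, 1], config.n_per_group)
    sample_sheet = pd.DataFrame(
        {"group": np.repeat(list(config.group_names), config.n_per_group)},
        index=pd.Index(samples, name="sample_id"),
    )

    ip_expect = config.scale * np.exp2(abundance_g) * meth_g            # (2, n)
    sup_expect = config.scale * np.exp2(abundance_g) * (1.0 - meth_g)

    noise_streams = ss_noise.spawn(len(samples))  # one stream per array
    cy5_cols, cy3_cols = {}, {}
    for s_idx, s in enumerate(samples):
        nrng = np.random.default_rng(noise_streams[s_idx])
        g = group_of[s_idx]
        ip = ip_expect[g][probe_tx] * np.exp2(nrng.normal(0.0, config.noise_sd, probe_tx.size))
        sup = sup_expect[g][probe_tx] * np.exp2(nrng.normal(0.0, config.noise_sd, probe_tx.size))
        cy5_cols[s] = ip
        cy3_cols[s] = sup

    frng = np.random.default_rng(ss_flags)
    flags = np.where(
        frng.random((probe_tx.size, len(samples))) < config.frac_absent_flags, "A", "P"
    ).astype(object)

    # spike-in probes: fixed level, fixed split, noise-free, always Present
    spike_rows = []
    for kind, count, frac in (("pos", config.n_spikein_pos, 0.9),
                              ("neg", config.n_spikein_neg, 0.0)):
        for j in range(count):
            spike_rows.append((f"SPIKE_{kind.upper()}_{j:02d}", kind,
                               config.spikein_level * frac,
                               config.spikein_level * (1.0 - frac)))

    probe_index = pd.Index(
        np.concatenate([probe_names, [r[0] for r in spike_rows]]), name="probe_id"
    )
    probes = pd.DataFrame(
        {
            "transcript_id": np.concatenate([transcript_id[probe_tx],
                                             [r[0] for r in spike_rows]]),
            "gene_symbol": np.concatenate([gene_symbol[probe_tx],
                                           [r[0] for r in spike_rows]]),
            "rna_class": np.concatenate([rna_class[probe_tx],
                                         ["mRNA"] * len(spike_rows)]),
            "spikein": np.concatenate([np.full(probe_tx.size, "none", dtype=object),
                                       [r[1] for r in spike_rows]]),
        },
        index=probe_index,
    )

    def full_channel(cols: dict, spike_col: int) -> pd.DataFrame:
        data = {}
        for s in samples:
            spike_vals = np.array([r[spike_col] for r in spike_rows], dtype=float)
            col = np.concatenate([cols[s], spike_vals])
            data[s] = np.where(col > 0, col, np.nan)  # zero intensity = missing
        return pd.DataFrame(data, index=probe_index)

    cy5 = full_channel(cy5_cols, 2)
    cy3 = full_channel(cy3_cols, 3)
    flags_full = pd.DataFrame(
        np.concatenate([flags, np.full((len(spike_rows), len(samples)), "P", dtype=object)]),
        index=probe_index, columns=samples,
    )

    raw = RawArraySet(probes=probes, samples=sample_sheet, cy5=cy5, cy3=cy3,
                      flags=flags_full)
    return raw, truth


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

def simulate_qpcr_plate(
    targets: list[str],
    effects: Mapping[str, Mapping[str, float]],
    seed: int = 0,
    *,
    sigma_ct: float = 0.2,
    base_ct: float = 24.0,
    reference: str = "U6",
    conditions: tuple[str, str] = GROUP_NAMES,
    n_duplicate_wells: int = 2,
) -> pd.DataFrame:
    """Simulate a qPCR plate with duplicate wells per target.

    ``effects[target]`` may carry:

    ``rel_quantity``
        true relative quantity of the target in the second condition versus
        the first (the calibrator); drives the expression (fraction="none")
        wells and the 2^-ddCt recovery.
    ``pct_input``
        true MeRIP %input for the target; drives paired MeRIP / Supernatant
        fraction wells (one condition, the first).

    Ct values follow ``Ct = base_ct - log2(quantity) + N(0, sigma_ct^2)``;
    the reference gene has quantity 1 in every condition.
    """
    if sigma_ct < 0:
        raise ValidationError("sigma_ct must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    well = 0

    def emit(target: str, fraction: str, condition: str, quantity: float) -> None:
        nonlocal well
        for rep in range(n_duplicate_wells):
            ct = base_ct - np.log2(quantity) + rng.normal(0.0, sigma_ct)
            rows.append(
                {"well": f"W{well:03d}", "target_id": target, "fraction": fraction,
                 "condition": condition, "replicate": rep + 1, "ct": float(ct)}
            )
            well += 1

    cal, other = conditions
    for target in targets:
        eff = effects.get(target, {})
        if "rel_quantity" in eff:
            emit(target, "none", cal, 1.0)
            emit(target, "none", other, float(eff["rel_quantity"]))
        if "pct_input" in eff:
            f = float(eff["pct_input"]) / 100.0
            if not 0.0 < f < 1.0:
                raise ValidationError(f"pct_input for {target!r} must be in (0, 100)")
            emit(target, "MeRIP", cal, f)
            emit(target, "Supernatant", cal, 1.0 - f)
    # endogenous reference, quantity 1 everywhere
    emit(reference, "none", cal, 1.0)
    emit(reference, "none", other, 1.0)
    return pd.DataFrame(rows)
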