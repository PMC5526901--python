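"""Synthetic flow-cytometry sample generator.

Emulates PBMC samples stained for MHC-multimer detection: a mixture of
debris, doublets, dead cells, non-T lymphocytes, CD3+CD8- T cells, and
CD8+ T cells of which a small configurable fraction binds the multimer.
Per-event channel intensities are lognormal on the raw linear scale;
per-lab variation enters as multiplicative gain shifts and inflated
spreads.  Every event carries a ground-truth population label, so
downstream gating and clustering can be scored exactly.

Two spike-in dilution designs are bundled as presets: a fivefold series
over seven steps starting at 1.7% multimer+ of live single lymphocytes,
and a twofold series over nine steps starting at 0.87% (CMV, PE channel)
with a pure-negative end sample.

The per-population intensity locations and spreads are artifact choices
of this generator (chosen to give a clearly separated multimer+
population over low background, as in a clean high-avidity staining);
they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .io import ChannelInfo, ChannelMismatchError, EventTable

POPULATIONS = (
    "debris",
    "doublet",
    "dead",
    "nonT_lymph",
    "CD3pos_CD8neg",
    "CD8pos_multimer_neg",
    "CD8pos_multimer_pos",
)

#: Labels that count as live single lymphocytes (the primary denominator).
LIVE_SINGLE_LABELS = frozenset(
    {"nonT_lymph", "CD3pos_CD8neg", "CD8pos_multimer_neg", "CD8pos_multimer_pos"}
)

#: Labels that count as CD8+ T cells (the secondary denominator).
CD8_LABELS = frozenset({"CD8pos_multimer_neg", "CD8pos_multimer_pos"})

MULTIMER_LABEL = "CD8pos_multimer_pos"

# ----------------------------------------------------------------------
# Sample composition defaults (fractions of total events / of live single
# lymphocytes).  Artifact choices representing a typical thawed PBMC run.
# ----------------------------------------------------------------------
DEBRIS_FRACTION = 0.06
DOUBLET_FRACTION = 0.04
DEAD_FRACTION = 0.06
LIVE_SINGLE_FRACTION = 1.0 - DEBRIS_FRACTION - DOUBLET_FRACTION - DEAD_FRACTION
NONT_OF_LSL = 0.30
CD3_CD8NEG_OF_LSL = 0.45
CD8_OF_LSL = 0.25  # CD8+ T cells as a fraction of live single lymphocytes

# Raw-scale (mean, CV) per role per population.  Scatter means are in
# arbitrary linear units ~[0, 2.5e5]; fluorescence separations are tuned so
# that positive/negative populations are distinct after arcsinh (cofactor
# 150), mimicking bright staining over low background.
_LYMPH_SCATTER = {"FSC-A": (50_000, 0.13), "SSC-A": (18_000, 0.30)}

CHANNEL_MODELS: dict[str, dict[str, tuple[float, float]]] = {
    "debris": {
        "FSC-A": (12_000, 0.35),
        "SSC-A": (6_000, 0.50),
        "viability": (2_000, 1.00),
        "dump": (300, 1.00),
        "CD3": (80, 1.00),
        "CD8": (80, 1.00),
        "multimer-PE": (50, 0.90),
        "multimer-APC": (50, 0.90),
    },
    "doublet": {
        **_LYMPH_SCATTER,  # FSC-A is doubled event-wise, see _draw_scatter
        "viability": (250, 0.60),
        "dump": (2_500, 0.90),
        "CD3": (2_000, 0.90),
        "CD8": (500, 1.00),
        "multimer-PE": (60, 0.80),
        "multimer-APC": (60, 0.80),
    },
    "dead": {
        **_LYMPH_SCATTER,
        "viability": (30_000, 0.35),
        "dump": (3_000, 0.80),
        "CD3": (1_500, 0.90),
        "CD8": (300, 1.00),
        "multimer-PE": (80, 0.90),
        "multimer-APC": (80, 0.90),
    },
    "nonT_lymph": {
        **_LYMPH_SCATTER,
        "viability": (200, 0.60),
        "dump": (5_000, 0.50),
        "CD3": (100, 0.80),
        "CD8": (120, 0.90),
        "multimer-PE": (60, 0.80),
        "multimer-APC": (60, 0.80),
    },
    "CD3pos_CD8neg": {
        **_LYMPH_SCATTER,
        "viability": (200, 0.60),
        "dump": (4_000, 0.50),  # CD4 is part of the dump mix
        "CD3": (5_000, 0.35),
        "CD8": (120, 0.90),
        "multimer-PE": (60, 0.80),
        "multimer-APC": (60, 0.80),
    },
    "CD8pos_multimer_neg": {
        **_LYMPH_SCATTER,
        "viability": (200, 0.60),
        "dump": (120, 0.80),
        "CD3": (5_000, 0.35),
        "CD8": (8_000, 0.30),
        "multimer-PE": (60, 0.80),
        "multimer-APC": (60, 0.80),
    },
    "CD8pos_multimer_pos": {
        **_LYMPH_SCATTER,
        "viability": (200, 0.60),
        "dump": (120, 0.80),
        "CD3": (5_500, 0.25),
        "CD8": (8_500, 0.25),
        "multimer-PE": (8_000, 0.20),
        "multimer-APC": (8_000, 0.20),
    },
}

#: Channel layout per role: (short_name, stain_label)
_CHANNEL_NAMES = {
    "FSC-A": ("FSC-A", None),
    "FSC-H": ("FSC-H", None),
    "SSC-A": ("SSC-A", None),
    "viability": ("APC-Cy7-A", "LiveDead"),
    "dump": ("FITC-A", "Dump"),
    "CD3": ("BV421-A", "CD3"),
    "CD8": ("PerCP-A", "CD8"),
    "multimer-PE": ("PE-A", "Multimer-PE"),
    "multimer-APC": ("APC-A", "Multimer-APC"),
}

DEFAULT_PANEL = ("viability", "CD3", "CD8", "multimer-PE")
SPIKEIN1_PANEL = ("viability", "dump", "CD8", "multimer-PE", "multimer-APC")
SPIKEIN2_PANEL = ("viability", "CD3", "CD8", "multimer-PE", "multimer-APC")


# ----------------------------------------------------------------------
# Specs
# ----------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """One cell population: its share of events and per-role lognormal
    intensity model (raw-scale mean and coefficient of variation)."""

    name: str
    fraction: float
    channel_means: Mapping[str, float]
    channel_cvs: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise ValueError(f"unknown population {self.name!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if any(cv <= 0 for cv in self.channel_cvs.values()):
            raise ValueError("channel_cvs must be positive")


@dataclass
class LabProfile:
    """Per-laboratory acquisition profile: multiplicative per-role gain
    shifts, a global spread multiplier, and which roles the panel stains."""

    lab_id: str = "lab-000"
    gain_shift: Mapping[str, float] = field(default_factory=dict)
    background_spread: float = 1.0
    panel: tuple[str, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain_shift.values()):
            raise ValueError("gain_shift factors must be positive")
        if self.background_spread <= 0:
            raise ValueError("background_spread must be positive")
        has_multimer = any(r.startswith("multimer") for r in self.panel)
        has_lineage = "CD3" in self.panel or "dump" in self.panel
        if not (has_multimer and "CD8" in self.panel and has_lineage):
            raise ValueError(
                "panel must include CD8 and a multimer channel plus CD3 or dump"
            )


@dataclass
class SpikeInDesign:
    """A serial-dilution experiment: starting multimer+ frequency ``f0``
    (% of live single lymphocytes), dilution factor ``dilution_factor``,
    ``n_steps`` samples, each of ``n_events_per_sample`` events, run in
    ``duplicates`` replicates, optionally ending with a pure negative."""

    f0: float = 1.7
    dilution_factor: float = 5.0
    n_steps: int = 7
    n_events_per_sample: int = 200_000
    duplicates: int = 2
    include_pure_negative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 <= 100.0:
            raise ValueError("f0 must lie in (0, 100]")
        if self.dilution_factor <= 1.0:
            raise ValueError("dilution_factor must exceed 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.duplicates < 1:
            raise ValueError("duplicates must be >= 1")


def panel_populations(
    multimer_pct_lsl: float | None = None,
    multimer_pct_cd8: float | None = None,
    channel_models: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> list[PopulationSpec]:
    """Build the default seven-population mixture with a chosen multimer+
    frequency, given either as % of live single lymphocytes or as % of
    CD8+ T cells (the two denominators used for reporting).
    """
    if (multimer_pct_lsl is None) == (multimer_pct_cd8 is None):
        raise ValueError("give exactly one of multimer_pct_lsl / multimer_pct_cd8")
    if multimer_pct_cd8 is not None:
        f_lsl = (multimer_pct_cd8 / 100.0) * CD8_OF_LSL
    else:
        f_lsl = multimer_pct_lsl / 100.0
    if not 0.0 <= f_lsl <= CD8_OF_LSL:
        raise ValueError(
            f"multimer+ fraction {f_lsl:.4f} of live single lymphocytes exceeds "
            f"the CD8 compartment ({CD8_OF_LSL})"
        )
    models = channel_models or CHANNEL_MODELS
    lsl = LIVE_SINGLE_FRACTION
    fractions = {
        "debris": DEBRIS_FRACTION,
        "doublet": DOUBLET_FRACTION,
        "dead": DEAD_FRACTION,
        "nonT_lymph": NONT_OF_LSL * lsl,
        "CD3pos_CD8neg": CD3_CD8NEG_OF_LSL * lsl,
        "CD8pos_multimer_neg": (CD8_OF_LSL - f_lsl) * lsl,
        "CD8pos_multimer_pos": f_lsl * lsl,
    }
    specs = []
    for name, frac in fractions.items():
        model = models[name]
        specs.append(
            PopulationSpec(
                name=name,
                fraction=frac,
                channel_means={r: mv[0] for r, mv in model.items()},
                channel_cvs={r: mv[1] for r, mv in model.items()},
            )
        )
    return specs


# ----------------------------------------------------------------------
# Donor presets.  Proficiency-panel donor responses are parameterized as
# % multimer+ of CD8+ T cells (pretest-defined response sizes); the two
# spike-in donors as % of live single lymphocytes.
# ----------------------------------------------------------------------
DONOR_PRESETS: dict[str, dict] = {
    "518-EBV": {"multimer_pct_cd8": 1.13, "panel": DEFAULT_PANEL},
    "518-FLU": {"multimer_pct_cd8": 0.09, "panel": DEFAULT_PANEL},
    "519-EBV": {"multimer_pct_cd8": 5.33, "panel": DEFAULT_PANEL},
    "519-FLU": {"multimer_pct_cd8": 0.04, "panel": DEFAULT_PANEL},
    "spikein1-positive": {"multimer_pct_lsl": 1.7, "panel": SPIKEIN1_PANEL},
    "spikein1-negative": {"multimer_pct_lsl": 0.0, "panel": SPIKEIN1_PANEL},
    "spikein2-positive": {"multimer_pct_lsl": 0.87, "panel": SPIKEIN2_PANEL},
    "spikein2-negative": {"multimer_pct_lsl": 0.0, "panel": SPIKEIN2_PANEL},
}

SPIKEIN_DESIGNS: dict[str, SpikeInDesign] = {
    "spikein1": SpikeInDesign(
        f0=1.7, dilution_factor=5.0, n_steps=7, duplicates=2,
        include_pure_negative=False,
    ),
    "spikein2": SpikeInDesign(
        f0=0.87, dilution_factor=2.0, n_steps=9, duplicates=1,
        include_pure_negative=True,
    ),
}


def preset_populations(donor: str) -> list[PopulationSpec]:
    """Population mixture for a named donor preset."""
    p = DONOR_PRESETS[donor]
    return panel_populations(
        multimer_pct_lsl=p.get("multimer_pct_lsl"),
        multimer_pct_cd8=p.get("multimer_pct_cd8"),
    )


def preset_profile(donor: str, lab_id: str = "lab-000") -> LabProfile:
    return LabProfile(lab_id=lab_id, panel=DONOR_PRESETS[donor]["panel"])


def noisy_lab_profile(lab_id: str, seed: int, panel: tuple[str, ...] = DEFAULT_PANEL,
                      spread: float = 1.4) -> LabProfile:
    """A lab with its own gains and extra spread, emulating the
    antibody/instrument heterogeneity of a multi-laboratory panel."""
    rng = np.random.default_rng(seed)
    gains = {
        role: float(np.exp(rng.normal(0.0, 0.25)))
        for role in panel
    }
    return LabProfile(lab_id=lab_id, gain_shift=gains,
                      background_spread=spread, panel=panel)


# ----------------------------------------------------------------------
# Event synthesis
# ----------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Draw n lognormal values with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _panel_channels(panel: Sequence[str]) -> list[ChannelInfo]:
    roles = ["FSC-A", "FSC-H", "SSC-A"] + [r for r in panel if r not in
                                           ("FSC-A", "FSC-H", "SSC-A")]
    chans = []
    for role in roles:
        short, stain = _CHANNEL_NAMES[role]
        chans.append(ChannelInfo(short_name=short, stain_label=stain, role=role))
    return chans


def simulate_donor(
    populations: Sequence[PopulationSpec],
    profile: LabProfile,
    n_events: int,
    seed: int,
) -> EventTable:
    """Simulate one stained sample from one donor under one lab profile.

    Population sizes are multinomial; intensities lognormal with the
    population's means scaled by the lab's gain shifts and CVs inflated by
    its background spread.  Doublets get FSC-A ~ 2x FSC-H so the singlet
    gate (FSC-H vs FSC-A) is meaningful; singlets sit near FSC-H = 0.95
    FSC-A.  Reproducible given `seed`.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    fractions = np.array([p.fraction for p in populations], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {fractions.sum()}, not 1")
    if not any(r.startswith("multimer") for r in profile.panel):
        raise ValueError("lab panel lacks a multimer channel role")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, fractions)
    channels = _panel_channels(profile.panel)
    roles = [c.role for c in channels]

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for pop, n in zip(populations, counts):
        if n == 0:
            continue
        block = np.empty((n, len(roles)))
        # scatter: FSC-A drawn, FSC-H derived, doublets doubled on the A axis
        fa_mean, fa_cv = pop.channel_means["FSC-A"], pop.channel_cvs["FSC-A"]
        base_fa = _lognormal(rng, fa_mean, fa_cv, n)
        fsc_h = base_fa * 0.95 * np.exp(rng.normal(0.0, 0.03, size=n))
        if pop.name == "doublet":
            fsc_a = 2.0 * fsc_h * np.exp(rng.normal(0.0, 0.05, size=n))
        else:
            fsc_a = base_fa
        for j, role in enumerate(roles):
            if role == "FSC-A":
                block[:, j] = fsc_a
            elif role == "FSC-H":
                block[:, j] = fsc_h
            else:
                mean = pop.channel_means[role]
                cv = pop.channel_cvs[role]
                if role not in ("FSC-A", "FSC-H", "SSC-A"):
                    mean *= profile.gain_shift.get(role, 1.0)
                    cv *= profile.background_spread
                block[:, j] = _lognormal(rng, mean, cv, n)
        blocks.append(block)
        labels.append(np.full(n, pop.name, dtype=object))

    values = np.concatenate(blocks, axis=0)
    label_arr = np.concatenate(labels)
    order = rng.permutation(values.shape[0])
    return EventTable(
        values=values[order],
        channels=channels,
        event_ids=np.arange(values.shape[0], dtype=np.int64),
        labels=label_arr[order],
        transform_state="raw",
    )


def mix_spikein(
    positive: EventTable,
    negative: EventTable,
    positive_fraction: float,
    n_events: int,
    seed: int,
) -> EventTable:
    """Mix events from a positive and a negative donor at a given ratio.

    Events are resampled (with replacement if a donor is smaller than its
    share) so the output has exactly `n_events` rows.  Labels are kept and
    donor-of-origin is recorded in ``source_index`` (1 = positive donor).
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    if positive.channel_names != negative.channel_names:
        diff = set(positive.channel_names) ^ set(negative.channel_names)
        raise ChannelMismatchError(f"donor channel sets differ: {sorted(diff)}")
    rng = np.random.default_rng(seed)
    n_pos = int(rng.binomial(n_events, positive_fraction))
    n_neg = n_events - n_pos
    parts, labels, sources = [], [], []
    for donor, n_take, tag in ((positive, n_pos, 1), (negative, n_neg, 0)):
        if n_take == 0:
            continue
        idx = rng.choice(donor.n_events, size=n_take,
                         replace=n_take > donor.n_events)
        parts.append(donor.values[idx])
        labels.append(donor.labels[idx] if donor.labels is not None
                      else np.full(n_take, "unknown", dtype=object))
        sources.append(np.full(n_take, tag, dtype=np.int64))
    values = np.concatenate(parts, axis=0)
    order = rng.permutation(n_events)
    return EventTable(
        values=values[order],
        channels=[replace(c) for c in positive.channels],
        event_ids=np.arange(n_events, dtype=np.int64),
        labels=np.concatenate(labels)[order],
        transform_state=positive.transform_state,
        source_index=np.concatenate(sources)[order],
    )


def theoretical_frequency(design: SpikeInDesign, k: int) -> float:
    """Theoretical multimer+ frequency (% of live single lymphocytes) at
    dilution step `k` (1-based): f0 * d^-(k-1)."""
    if not 1 <= k <= design.n_steps:
        raise IndexError(f"step {k} outside 1..{design.n_steps}")
    return design.f0 * design.dilution_factor ** (-(k - 1))


class DilutionSample(NamedTuple):
    table: EventTable
    theoretical_pct: float
    step: int
    duplicate: int
    seed: int


def make_dilution_series(
    design: SpikeInDesign,
    positive: EventTable,
    negative: EventTable,
) -> list[DilutionSample]:
    """Generate the full dilution series: for step k the positive donor is
    mixed in at fraction d^-(k-1), each step replicated `duplicates` times
    under distinct sub-seeds; optionally a pure-negative sample is
    appended (theoretical frequency 0)."""
    out: list[DilutionSample] = []
    for k in range(1, design.n_steps + 1):
        frac = design.dilution_factor ** (-(k - 1))
        theo = theoretical_frequency(design, k)
        for dup in range(design.duplicates):
            sub_seed = (design.seed * 1_000_003 + k * 101 + dup) % (2**31)
            table = mix_spikein(positive, negative, frac,
                                design.n_events_per_sample, sub_seed)
            out.append(DilutionSample(table, theo, k, dup, sub_seed))
    if design.include_pure_negative:
        sub_seed = (design.seed * 1_000_003 + (design.n_steps + 1) * 101) % (2**31)
        table = mix_spikein(positive, negative, 0.0,
                            design.n_events_per_sample, sub_seed)
        out.append(DilutionSample(table, 0.0, design.n_steps + 1, 0, sub_seed))
    return out


# ----------------------------------------------------------------------
# Ground-truth bookkeeping
# ----------------------------------------------------------------------


def true_frequencies(table: EventTable) -> dict[str, float]:
    """Label-derived frequencies: multimer+ as % of live single lymphocytes
    and as % of CD8+ T cells, plus the raw counts."""
    if table.labels is None:
        raise ValueError("table carries no ground-truth labels")
    labels = table.labels
    n_lsl = int(np.isin(labels, list(LIVE_SINGLE_LABELS)).sum())
    n_cd8 = int(np.isin(labels, list(CD8_LABELS)).sum())
    n_pos = int((labels == MULTIMER_LABEL).sum())
    return {
        "n_live_single": n_lsl,
        "n_cd8": n_cd8,
        "n_multimer_pos": n_pos,
        "pct_of_live_single": 100.0 * n_pos / n_lsl if n_lsl else float("nan"),
        "pct_of_cd8": 100.0 * n_pos / n_cd8 if n_cd8 else float("nan"),
    }
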