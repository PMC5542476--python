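"""Synthetic expression cohorts with planted effects and known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real case/control blood-transcriptome cohorts:

* per-gene log2 baselines drawn uniformly over a stated intensity range
  (a lognormal population on the linear scale);
* i.i.d. Gaussian log2 noise per sample, with optional heavy-tail
  contamination to exercise the median-vs-mean rationale;
* multiplicative case effects planted on designated genes (additive
  log2(FC));
* latent single-factor co-expression blocks (one loading per block) that
  mimic the virus-response and bacteria-response sub-networks;
* multiple probes per gene with probe-level offsets and noise;
* injected missing values and sub-floor intensities so the QC path is
  exercised.

``paper_scale_study`` builds the default 20-cohort discovery design: 4
viral cohorts planting the VRG panel with per-cohort mean FC drawn in
[4.97, 17.42], 4 bacterial cohorts planting the BRG panel in [4.90, 15.91],
and 12 mixed cohorts re-using one panel each at moderate FC.  All
randomness flows from a single integer seed through ``numpy``'s PCG64
generator, so identical specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenePanel

__all__ = [
    "Block",
    "CohortSpec",
    "SimulatedCohort",
    "StudyDesignSpec",
    "EventSpec",
    "LongitudinalSpec",
    "generate_cohort",
    "generate_study",
    "generate_discrimination_cohort",
    "generate_longitudinal",
    "paper_scale_study",
    "default_panel_names",
]

FLOOR_LOG2 = float(np.log2(100.0))

# Printed per-panel mean-FC ranges the discovery cohorts emulate.
VIRAL_MEAN_FC_RANGE = (4.97, 17.42)
BACTERIAL_MEAN_FC_RANGE = (4.90, 15.91)


@dataclass(frozen=True)
class Block:
    """A latent-factor co-expression block: one factor, one loading."""

    genes: tuple[str, ...]
    loading: float = 0.5


@dataclass
class CohortSpec:
    """Everything needed to generate one case/control cohort."""

    n_genes: int = 1000
    n_case: int = 20
    n_control: int = 20
    baseline_mean_range: tuple[float, float] = (7.0, 12.0)
    baseline_sd: float = 0.0  # extra gene-level jitter on the baseline
    noise_sd: float = 0.5  # log2 within-group noise
    heavy_tail_fraction: float = 0.0  # samples of 3x-sd contamination noise
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    coexpression_blocks: tuple[Block, ...] = ()
    missing_rate: float = 0.0
    probes_per_gene: tuple[int, ...] = (1,)
    probe_offset_sd: float = 0.25
    probe_noise_sd: float = 0.1
    sub_floor_rate: float = 0.0
    gene_names: tuple[str, ...] | None = None
    class_label: str = "disease"
    name: str = "cohort"
    seed: int | None = None

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.sub_floor_rate, self.heavy_tail_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if any(fc <= 0 for fc in self.planted_effects.values()):
            raise ValueError("planted fold changes must be positive")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control")

    def resolve_gene_names(self) -> list[str]:
        if self.gene_names is not None:
            if len(self.gene_names) != self.n_genes:
                raise ValueError("gene_names length must equal n_genes")
            return [g.upper() for g in self.gene_names]
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass
class SimulatedCohort:
    name: str
    probes: pd.DataFrame  # probe x sample log2 intensities (NaN = missing)
    probe_map: pd.DataFrame  # probe_id, gene_symbol
    genes: pd.DataFrame  # noise-free probe-collapse view: gene x sample
    metadata: pd.DataFrame  # indexed by sample_id: group, class_label
    truth: dict


def _rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_cohort(spec: CohortSpec, seed=None) -> SimulatedCohort:
    """Draw one cohort; ``seed`` (or ``spec.seed``) fixes all randomness."""
    rng = _rng_from(spec.seed if seed is None else seed)
    genes = spec.resolve_gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    missing_planted = [g for g in spec.planted_effects if g.upper() not in gene_index]
    if missing_planted:
        raise ValueError(f"planted genes not in gene universe: {missing_planted}")

    n_samples = spec.n_case + spec.n_control
    case_cols = [f"case_{i:03d}" for i in range(spec.n_case)]
    ctrl_cols = [f"ctrl_{i:03d}" for i in range(spec.n_control)]
    samples = case_cols + ctrl_cols

    lo, hi = spec.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=spec.n_genes)
    if spec.baseline_sd > 0:
        baseline = baseline + rng.normal(0.0, spec.baseline_sd, size=spec.n_genes)

    values = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, n_samples)
    )
    if spec.heavy_tail_fraction > 0:
        contam = rng.random((spec.n_genes, n_samples)) < spec.heavy_tail_fraction
        values = values + contam * rng.normal(
            0.0, 3.0 * spec.noise_sd, size=(spec.n_genes, n_samples)
        )
    for block in spec.coexpression_blocks:
        rows = [gene_index[g.upper()] for g in block.genes if g.upper() in gene_index]
        factor = rng.normal(0.0, 1.0, size=n_samples)
        values[rows] += block.loading * factor
    for g, fc in spec.planted_effects.items():
        values[gene_index[g.upper()], : spec.n_case] += np.log2(fc)

    gene_df = pd.DataFrame(values, index=genes, columns=samples)

    # probe expansion: each gene gets k probes with a fixed offset + noise
    n_probes_per = rng.choice(spec.probes_per_gene, size=spec.n_genes)
    probe_rows = []
    probe_ids = []
    map_rows = []
    for i, g in enumerate(genes):
        for p in range(int(n_probes_per[i])):
            pid = f"{g}_p{p}"
            offset = rng.normal(0.0, spec.probe_offset_sd) if n_probes_per[i] > 1 else 0.0
            row = values[i] + offset + rng.normal(
                0.0, spec.probe_noise_sd, size=n_samples
            )
            probe_rows.append(row)
            probe_ids.append(pid)
            map_rows.append((pid, g))
    probes = np.vstack(probe_rows)

    if spec.sub_floor_rate > 0:
        mask = rng.random(probes.shape) < spec.sub_floor_rate
        probes = np.where(mask, rng.uniform(4.0, FLOOR_LOG2, size=probes.shape), probes)
    if spec.missing_rate > 0:
        mask = rng.random(probes.shape) < spec.missing_rate
        probes = np.where(mask, np.nan, probes)

    probe_df = pd.DataFrame(probes, index=probe_ids, columns=samples)
    probe_df.index.name = "id"
    probe_map = pd.DataFrame(map_rows, columns=["probe_id", "gene_symbol"])

    metadata = pd.DataFrame(
        {
            "group": ["case"] * spec.n_case + ["control"] * spec.n_control,
            "class_label": [spec.class_label] * spec.n_case
            + ["healthy"] * spec.n_control,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = {
        "planted_effects": {g.upper(): float(fc) for g, fc in spec.planted_effects.items()},
        "blocks": [tuple(b.genes) for b in spec.coexpression_blocks],
        "case_ids": case_cols,
        "control_ids": ctrl_cols,
    }
    return SimulatedCohort(
        name=spec.name,
        probes=probe_df,
        probe_map=probe_map,
        genes=gene_df,
        metadata=metadata,
        truth=truth,
    )


@dataclass
class StudyDesignSpec:
    """A multi-cohort discovery design sharing true VRG/BRG panels."""

    cohorts: tuple[CohortSpec, ...]
    vrg: tuple[str, ...]
    brg: tuple[str, ...]
    viral_cohorts: tuple[str, ...] = ()
    bacterial_cohorts: tuple[str, ...] = ()
    master_seed: int | None = None

    def __post_init__(self) -> None:
        for spec in self.cohorts:
            universe = set(spec.resolve_gene_names())
            for g in (*self.vrg, *self.brg):
                if g.upper() not in universe:
                    raise ValueError(
                        f"panel gene {g} missing from cohort {spec.name} universe"
                    )


def default_panel_names(n_vrg: int = 10, n_brg: int = 10) -> tuple[list[str], list[str]]:
    vrg = [f"VRG{i:02d}" for i in range(1, n_vrg + 1)]
    brg = [f"BRG{i:02d}" for i in range(1, n_brg + 1)]
    return vrg, brg


def paper_scale_study(
    master_seed: int,
    n_genes: int = 1000,
    n_case: int = 20,
    n_control: int = 20,
    noise_sd: float = 0.7,
    n_viral: int = 4,
    n_bacterial: int = 4,
    n_mixed: int = 12,
    mixed_fc_range: tuple[float, float] = (3.0, 8.0),
    missing_rate: float = 0.01,
    fc_spread_log2: float = 0.2,
) -> StudyDesignSpec:
    """The default 20-cohort discovery design with known VRG/BRG truth.

    Viral/bacterial cohorts plant their panel with per-cohort mean FC drawn
    uniformly in the stated per-panel ranges; per-gene FCs scatter around
    the cohort mean by ``fc_spread_log2`` on the log2 scale.  Mixed cohorts
    (autoimmune/other diseases) alternate between planting the VRG and the
    BRG panel at moderate FC, giving every panel gene a dysregulation
    frequency well above the candidate cutoff.
    """
    rng = _rng_from(master_seed)
    vrg, brg = default_panel_names()
    background = [f"G{i:05d}" for i in range(n_genes - 20)]
    gene_names = tuple(vrg + brg + background)

    def planted(panel_genes: Sequence[str], mean_fc: float) -> dict[str, float]:
        spread = rng.normal(0.0, fc_spread_log2, size=len(panel_genes))
        return {g: float(mean_fc * 2.0**d) for g, d in zip(panel_genes, spread)}

    cohorts: list[CohortSpec] = []
    blocks = (Block(genes=tuple(vrg), loading=0.4), Block(genes=tuple(brg), loading=0.4))

    def base(name: str, label: str, effects: dict[str, float]) -> CohortSpec:
        return CohortSpec(
            n_genes=n_genes,
            n_case=n_case,
            n_control=n_control,
            noise_sd=noise_sd,
            planted_effects=effects,
            coexpression_blocks=blocks,
            missing_rate=missing_rate,
            gene_names=gene_names,
            class_label=label,
            name=name,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    viral_ids = [f"viral_{i}" for i in range(n_viral)]
    for name in viral_ids:
        mean_fc = rng.uniform(*VIRAL_MEAN_FC_RANGE)
        cohorts.append(base(name, "viral", planted(vrg, mean_fc)))
    bacterial_ids = [f"bacterial_{i}" for i in range(n_bacterial)]
    for name in bacterial_ids:
        mean_fc = rng.uniform(*BACTERIAL_MEAN_FC_RANGE)
        cohorts.append(base(name, "bacterial", planted(brg, mean_fc)))
    for i in range(n_mixed):
        panel_genes = vrg if i % 2 == 0 else brg
        mean_fc = rng.uniform(*mixed_fc_range)
        cohorts.append(base(f"mixed_{i}", "mixed", planted(panel_genes, mean_fc)))

    return StudyDesignSpec(
        cohorts=tuple(cohorts),
        vrg=tuple(vrg),
        brg=tuple(brg),
        viral_cohorts=tuple(viral_ids),
        bacterial_cohorts=tuple(bacterial_ids),
        master_seed=master_seed,
    )


def generate_study(design: StudyDesignSpec) -> dict[str, SimulatedCohort]:
    """Generate every cohort of a design (seeds fixed in the cohort specs)."""
    out: dict[str, SimulatedCohort] = {}
    for spec in design.cohorts:
        out[spec.name] = generate_cohort(spec)
    return out


def generate_discrimination_cohort(
    panel: GenePanel | None = None,
    n_viral: int = 40,
    n_bacterial: int = 40,
    n_control: int = 20,
    n_genes: int = 200,
    viral_fc_range: tuple[float, float] = VIRAL_MEAN_FC_RANGE,
    bacterial_fc_range: tuple[float, float] = BACTERIAL_MEAN_FC_RANGE,
    noise_sd: float = 0.7,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GenePanel]:
    """A mixed viral/bacterial cohort for end-to-end discrimination tests.

    Returns (gene-level log2 matrix, metadata with class_label in
    {viral, bacterial, healthy}, the panel used).  Viral cases get the VRG
    panel elevated, bacterial cases the BRG panel, at per-gene FCs drawn
    uniformly in the stated ranges.
    """
    rng = _rng_from(seed)
    if panel is None:
        vrg, brg = default_panel_names()
        panel = GenePanel(vrg=vrg, brg=brg)
    background = [f"G{i:05d}" for i in range(n_genes - len(panel.genes))]
    genes = panel.genes + background
    n_samples = n_viral + n_bacterial + n_control
    baseline = rng.uniform(7.0, 12.0, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n_samples))

    gene_row = {g: i for i, g in enumerate(genes)}
    vfc = rng.uniform(*viral_fc_range, size=len(panel.vrg))
    bfc = rng.uniform(*bacterial_fc_range, size=len(panel.brg))
    for g, fc in zip(panel.vrg, vfc):
        values[gene_row[g], :n_viral] += np.log2(fc)
    for g, fc in zip(panel.brg, bfc):
        values[gene_row[g], n_viral : n_viral + n_bacterial] += np.log2(fc)

    samples = (
        [f"viral_{i:03d}" for i in range(n_viral)]
        + [f"bact_{i:03d}" for i in range(n_bacterial)]
        + [f"ctrl_{i:03d}" for i in range(n_control)]
    )
    expr = pd.DataFrame(values, index=genes, columns=samples)
    metadata = pd.DataFrame(
        {
            "group": ["case"] * (n_viral + n_bacterial) + ["control"] * n_control,
            "class_label": ["viral"] * n_viral
            + ["bacterial"] * n_bacterial
            + ["healthy"] * n_control,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return expr, metadata, panel


@dataclass(frozen=True)
class EventSpec:
    """A multiplicative immune event on one panel over a day window."""

    start_day: int
    duration: int
    panel: str  # "vrg" or "brg"
    fold: float

    def __post_init__(self) -> None:
        if self.panel not in {"vrg", "brg"}:
            raise ValueError("event panel must be 'vrg' or 'brg'")
        if self.fold <= 0 or self.duration < 1:
            raise ValueError("fold must be positive and duration >= 1")

    @property
    def days(self) -> range:
        return range(self.start_day, self.start_day + self.duration)


@dataclass
class LongitudinalSpec:
    """A single-subject panel time series with planted events.

    Baseline fluctuation follows a per-gene AR(1) process with stationary
    standard deviation ``noise_sd`` and autocorrelation ``ar_rho``; events
    add log2(fold) to all genes of the affected panel inside their window.
    """

    panel: GenePanel
    timepoints: tuple[int, ...] = tuple(range(0, 400, 10))
    baseline_range: tuple[float, float] = (7.0, 12.0)
    noise_sd: float = 0.3
    ar_rho: float = 0.6
    events: tuple[EventSpec, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if not 0.0 <= self.ar_rho < 1.0:
            raise ValueError("ar_rho must be in [0, 1)")
        by_panel: dict[str, list[EventSpec]] = {"vrg": [], "brg": []}
        for ev in self.events:
            for other in by_panel[ev.panel]:
                if ev.days.start < other.days.stop and other.days.start < ev.days.stop:
                    raise ValueError(
                        f"overlapping {ev.panel} event windows: {other} vs {ev}"
                    )
            by_panel[ev.panel].append(ev)


def generate_longitudinal(spec: LongitudinalSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate the panel time series; returns (genes x days matrix, truth)."""
    rng = _rng_from(spec.seed)
    genes = spec.panel.genes
    days = np.asarray(spec.timepoints)
    n_t = len(days)
    baseline = rng.uniform(*spec.baseline_range, size=len(genes))

    innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_rho**2)
    noise = np.empty((len(genes), n_t))
    noise[:, 0] = rng.normal(0.0, spec.noise_sd, size=len(genes))
    for t in range(1, n_t):
        noise[:, t] = spec.ar_rho * noise[:, t - 1] + rng.normal(
            0.0, innov_sd, size=len(genes)
        )
    values = baseline[:, None] + noise

    vrg_rows = [i for i, g in enumerate(genes) if g in set(spec.panel.vrg)]
    brg_rows = [i for i, g in enumerate(genes) if g in set(spec.panel.brg)]
    for ev in spec.events:
        cols = [j for j, d in enumerate(days) if d in ev.days]
        rows = vrg_rows if ev.panel == "vrg" else brg_rows
        for j in cols:
            values[rows, j] += np.log2(ev.fold)

    series = pd.DataFrame(values, index=list(genes), columns=list(days))
    truth = {
        "events": [
            {
                "start_day": ev.start_day,
                "duration": ev.duration,
                "panel": ev.panel,
                "fold": ev.fold,
                "days": [int(d) for d in days if d in ev.days],
            }
            for ev in spec.events
        ],
        "baseline": {g: float(b) for g, b in zip(genes, baseline)},
    }
    return series, truth
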