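"""Synthetic field-trial data with known ground truth.

The generator emulates the structure of a multi-year potato drought-
tolerance marker study so that every pipeline stage can be exercised with
a recorded truth:

* **Yields** — 31 cultivars grown in six experimental trials with paired
  control/drought arms. Each cultivar carries a latent tolerance effect
  tau (its proportional yield advantage under drought); drought yield is
  control yield x (1 - trial severity) x (1 + tau) x replicate noise, so
  DRYM recomputed from the table recovers tau up to replicate noise and
  the per-trial stress index recovers the planted severity.

* **Feature matrices** — a metabolite block (115 features, intensities on
  a log10 scale spanning ~4-6 decades, delivered as raw intensities) and
  a transcript block (43 features, delivered as log10 relative
  expression). A minority of features per block is class-informative:
  their means shift by ``effect_size`` noise-SD units per tolerance class,
  in control and drought samples alike (constitutive markers). Technical
  structure is added on the log scale: per-campaign batch offsets, a
  linear run-order drift, and cells missing completely at random (an
  optional left-censored mode masks low-intensity cells preferentially).
  Experimental-trial samples carry both treatment arms; agronomic-trial
  samples are control-like only.

* **qPCR tables** — long-format Ct values for stable reference genes
  (low CV, no factor effects), unstable decoys (planted treatment or
  cultivar shifts) and target genes whose Ct encodes a planted log10
  expression through the dCt identity, so normalization can be checked by
  round-trip.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .tolerance import TOLERANCE_CLASSES

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_yields",
    "simulate_features",
    "simulate_qpcr",
    "simulate_dataset",
]


@dataclasses.dataclass
class SimulationDesign:
    """Parameters of the synthetic study.

    Defaults mirror the scale of the emulated study: 31 cultivars, six
    experimental trials (metabolites profiled in five of them with three
    replicate pools per cell -> 930 training samples; transcripts in three
    trials with one pool per cell -> 186), 16 agronomic validation trials
    (metabolites in all 16 -> 496 samples; transcripts in six -> 186),
    115 metabolite and 43 transcript features with 5.5% / 2.2% missing
    cells. Tolerance spread and yield noise are set so that cultivar
    effects dominate trial noise, and marker effect sizes produce the
    high-single-digit OOB error regime of constitutive marker panels.
    """

    n_cultivars: int = 31
    n_experimental_trials: int = 6
    n_agronomic_trials: int = 16
    # block-specific trial coverage (indices into the trial lists)
    metabolite_experimental_trials: int = 5
    metabolite_agronomic_trials: int = 16
    transcript_experimental_trials: int = 3
    transcript_agronomic_trials: int = 6
    metabolite_replicates: int = 3
    transcript_replicates: int = 1
    # features
    n_metabolites: int = 115
    n_transcripts: int = 43
    n_informative_metabolites: int = 10
    n_informative_transcripts: int = 8
    n_stress_responsive: int = 0  # treatment-shifted confounder features
    effect_size: float = 1.0  # mean adjacent-class separation in noise-SD units
    cultivar_sd: float = 0.0  # optional cultivar-level offsets on informative features
    noise_sd: float = 1.0
    batch_effect_sd: float = 0.5
    sequence_effect_sd: float = 0.3
    missing_rate_metabolites: float = 0.055
    missing_rate_transcripts: float = 0.022
    left_censored: bool = False
    # yields
    base_yield: float = 10.0  # t/ha tuber starch
    cultivar_yield_sd: float = 0.15  # log-scale spread of yield potential
    replicate_cv: float = 0.01  # plot-level multiplicative noise
    n_yield_replicates: int = 4
    severity_range: tuple = (0.2, 0.5)  # drought severity of experimental trials
    tolerance_sd: float = 0.06  # spread of the latent tolerance effect tau
    # qPCR
    n_reference_stable: int = 4
    n_reference_decoys: int = 11
    n_qpcr_targets: int = 8
    reference_ct_noise: float = 1.0  # across-sample Ct spread (CV ~ 0.05 at Ct 20)
    target_ct_noise: float = 0.1

    def __post_init__(self) -> None:
        if self.n_informative_metabolites > self.n_metabolites:
            raise ValueError("more informative metabolites than metabolite features")
        if self.n_informative_transcripts > self.n_transcripts:
            raise ValueError("more informative transcripts than transcript features")
        for rate in (self.missing_rate_metabolites, self.missing_rate_transcripts):
            if not 0.0 <= rate < 0.5:
                raise ValueError(f"missing rate must lie in [0, 0.5), got {rate}")
        for count in (self.n_cultivars, self.n_experimental_trials, self.n_metabolites,
                      self.n_transcripts, self.n_yield_replicates):
            if count < 1:
                raise ValueError("all design counts must be >= 1")

    # -- identifier helpers ----------------------------------------------
    @property
    def cultivars(self) -> list:
        return [f"C{i + 1:02d}" for i in range(self.n_cultivars)]

    @property
    def experimental_trials(self) -> list:
        return [f"F{i + 1}" for i in range(self.n_experimental_trials)]

    @property
    def agronomic_trials(self) -> list:
        return [f"A{i + 1}" for i in range(self.n_agronomic_trials)]

    def block_trials(self, block: str) -> tuple[list, list]:
        """(experimental, agronomic) trial ids covered by a feature block."""
        if block == "metabolite":
            return (
                self.experimental_trials[: self.metabolite_experimental_trials],
                self.agronomic_trials[: self.metabolite_agronomic_trials],
            )
        if block == "transcript":
            return (
                self.experimental_trials[: self.transcript_experimental_trials],
                self.agronomic_trials[: self.transcript_agronomic_trials],
            )
        raise ValueError(f"unknown block {block!r}")

    def block_features(self, block: str) -> list:
        if block == "metabolite":
            return [f"M{i + 1:03d}" for i in range(self.n_metabolites)]
        return [f"T{i + 1:03d}" for i in range(self.n_transcripts)]

    def sample_frame(self, block: str) -> pd.DataFrame:
        """Deterministic sample metadata for one feature block.

        Experimental trials contribute both treatment arms with the block's
        replicate count; agronomic trials contribute one control-like pool
        per cultivar. Batch is the measurement campaign (one per trial).
        """
        exp, agro = self.block_trials(block)
        reps = self.metabolite_replicates if block == "metabolite" else self.transcript_replicates
        rows = []
        for trial in exp:
            for cultivar in self.cultivars:
                for treatment in ("control", "drought"):
                    for r in range(1, reps + 1):
                        rows.append((f"{trial}_{cultivar}_{treatment}_r{r}", cultivar,
                                     trial, treatment, trial, "experimental"))
        for trial in agro:
            for cultivar in self.cultivars:
                rows.append((f"{trial}_{cultivar}_control_r1", cultivar, trial,
                             "control", trial, "agronomic"))
        meta = pd.DataFrame(
            rows, columns=["sample", "cultivar", "trial", "treatment", "batch", "trial_type"]
        ).set_index("sample")
        meta["sequence"] = np.arange(1, len(meta) + 1)
        return meta


@dataclasses.dataclass
class GroundTruth:
    """Planted parameters recorded alongside a simulated dataset."""

    tolerance: dict  # cultivar -> latent tolerance effect tau
    true_class: dict  # cultivar -> low / intermediate / high
    severity: dict  # experimental trial -> planted drought severity (= true SI)
    informative_features: dict = dataclasses.field(default_factory=dict)  # block -> ids
    batch_offsets: dict = dataclasses.field(default_factory=dict)  # block -> DataFrame
    reference_genes: list = dataclasses.field(default_factory=list)
    decoy_genes: dict = dataclasses.field(default_factory=dict)  # gene -> planted defect
    target_expression: pd.DataFrame | None = None  # planted log10 expression

    def to_json(self, path) -> None:
        payload = {
            "tolerance": self.tolerance,
            "true_class": self.true_class,
            "severity": self.severity,
            "informative_features": self.informative_features,
            "reference_genes": self.reference_genes,
            "decoy_genes": self.decoy_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _tertile_classes(values: pd.Series) -> dict:
    """Tertile labels with boundary values going to the lower class."""
    q_low, q_high = np.quantile(values.to_numpy(float), [1 / 3, 2 / 3])
    out = {}
    for key, v in values.items():
        out[key] = "low" if v <= q_low else ("intermediate" if v <= q_high else "high")
    return out


def simulate_yields(design: SimulationDesign, seed: int = 0):
    """Starch-yield table for the experimental trials, plus ground truth.

    Control replicate yields are cultivar-specific log-normal draws around
    the design's base yield; drought replicates are scaled by the trial
    severity and the cultivar's latent tolerance effect. Returns
    ``(yield_table, ground_truth)``.
    """
    rng = np.random.default_rng(seed)
    cultivars = design.cultivars
    tau = rng.normal(0.0, design.tolerance_sd, size=len(cultivars))
    tau = pd.Series(tau, index=cultivars)
    severity = {
        t: float(s)
        for t, s in zip(
            design.experimental_trials,
            rng.uniform(*design.severity_range, size=design.n_experimental_trials),
        )
    }
    cult_mean = design.base_yield * np.exp(
        rng.normal(0.0, design.cultivar_yield_sd, size=len(cultivars))
    )
    cult_mean = pd.Series(cult_mean, index=cultivars)

    rows = []
    for trial in design.experimental_trials:
        sev = severity[trial]
        for cultivar in cultivars:
            for r in range(1, design.n_yield_replicates + 1):
                noise_c = np.exp(rng.normal(0.0, design.replicate_cv))
                noise_d = np.exp(rng.normal(0.0, design.replicate_cv))
                control = cult_mean[cultivar] * noise_c
                drought = (
                    cult_mean[cultivar] * (1.0 - sev) * (1.0 + tau[cultivar]) * noise_d
                )
                rows.append((cultivar, trial, "control", f"r{r}", control))
                rows.append((cultivar, trial, "drought", f"r{r}", max(drought, 0.0)))
    yields = pd.DataFrame(
        rows, columns=["cultivar", "trial", "treatment", "replicate", "starch_yield"]
    )
    truth = GroundTruth(
        tolerance={c: float(tau[c]) for c in cultivars},
        true_class=_tertile_classes(tau),
        severity=severity,
    )
    return yields, truth


_CLASS_SHIFT = {c: i - 1 for i, c in enumerate(TOLERANCE_CLASSES)}  # low=-1 .. high=+1


def simulate_features(
    design: SimulationDesign, truth: GroundTruth, block: str = "metabolite", seed: int = 0
) -> FeatureMatrix:
    """One feature block (metabolite or transcript) with metadata and gaps.

    Informative features shift their mean by ``effect_size`` noise-SD units
    per tolerance class in both treatment arms, plus a cultivar-level
    offset within class; the remaining features are pure noise. Batch
    offsets and a linear run-order drift are added on the log scale, then
    cells are masked at the block's missing rate. Metabolite values are
    returned as raw intensities (10^log-value, expecting a downstream log
    transform); transcript values are returned on the log10 expression
    scale directly. Planted informative ids and batch offsets are recorded
    in ``truth``.
    """
    rng = np.random.default_rng(seed)
    meta = design.sample_frame(block)
    features = design.block_features(block)
    n_inf = (
        design.n_informative_metabolites
        if block == "metabolite"
        else design.n_informative_transcripts
    )
    informative = features[:n_inf]
    n_stress = min(design.n_stress_responsive, len(features) - n_inf)
    stress_responsive = features[n_inf : n_inf + n_stress]
    missing_rate = (
        design.missing_rate_metabolites
        if block == "metabolite"
        else design.missing_rate_transcripts
    )

    n, p = len(meta), len(features)
    base = rng.uniform(4.0, 6.0, size=p) if block == "metabolite" else rng.uniform(-1.0, 1.0, size=p)
    X = np.tile(base, (n, 1))

    # Class-ordered constitutive shifts on the informative features. Each
    # marker discriminates one part of the tolerance range more sharply
    # than the other: the intermediate-class mean sits at a random point
    # between the low and high means (monotone in class), with the
    # low-to-high span fixed at 2 x effect_size so the *average* adjacent
    # separation is effect_size noise-SD units.
    class_of = truth.true_class
    shift = design.effect_size * design.noise_sd
    u = rng.uniform(0.05, 0.95, size=n_inf)  # position of the intermediate mean
    raw_means = np.vstack([np.zeros(n_inf), 2.0 * u, 2.0 * np.ones(n_inf)])
    class_means = (raw_means - raw_means.mean(axis=0)) * shift  # rows: low/int/high
    class_row = {c: i for i, c in enumerate(TOLERANCE_CLASSES)}
    cult_offsets = {
        c: rng.normal(0.0, design.cultivar_sd, size=n_inf) for c in design.cultivars
    }
    cultivar_arr = meta["cultivar"].to_numpy()
    for i, cultivar in enumerate(cultivar_arr):
        X[i, :n_inf] += class_means[class_row[class_of[cultivar]]] + cult_offsets[cultivar]

    # optional stress-responsive confounders: drought shift, no class signal
    if n_stress:
        drought = (meta["treatment"] == "drought").to_numpy()
        X[drought, n_inf : n_inf + n_stress] += shift

    # technical structure: batch offsets and run-order drift
    batches = sorted(meta["batch"].unique())
    offsets = pd.DataFrame(
        rng.normal(0.0, design.batch_effect_sd, size=(len(batches), p)),
        index=batches,
        columns=features,
    )
    X += offsets.loc[meta["batch"]].to_numpy()
    slope = rng.normal(0.0, design.sequence_effect_sd, size=p)
    seq = (meta["sequence"].to_numpy(float) - 1) / max(n - 1, 1) - 0.5
    X += np.outer(seq, slope)

    X += rng.normal(0.0, design.noise_sd, size=(n, p))

    # missing cells: MCAR, or preferentially low-intensity if left-censored
    if missing_rate > 0:
        if design.left_censored:
            # mask the missing_rate quantile per feature, softened by noise
            score = X + rng.normal(0.0, design.noise_sd, size=(n, p))
            cut = np.quantile(score, missing_rate, axis=0)
            mask = score < cut
        else:
            mask = rng.random(size=(n, p)) < missing_rate
        # never blank out a full sample or feature
        mask[:, mask.all(axis=0)] = False
        mask[mask.all(axis=1), :] = False
        X = np.where(mask, np.nan, X)

    values = pd.DataFrame(X, index=meta.index, columns=features)
    if block == "metabolite":
        values = 10.0**values
    truth.informative_features[block] = list(informative)
    truth.batch_offsets[block] = offsets
    return FeatureMatrix(values, meta)


def simulate_qpcr(
    design: SimulationDesign,
    truth: GroundTruth,
    n_reference_stable: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format qPCR Ct table for reference-gene screening.

    Samples cover every cultivar under field and glasshouse cultivation and
    both treatments. Stable reference genes draw Ct around a gene-specific
    base with low noise (CV well below 0.07); decoy genes carry either a
    +2-cycle drought shift or cultivar-specific offsets; target genes
    encode a planted log10 expression via Ct = reference mean - log2
    expression, recorded in ``truth.target_expression``.
    """
    rng = np.random.default_rng(seed)
    n_stable = design.n_reference_stable if n_reference_stable is None else n_reference_stable
    stable = [f"REF{i + 1:02d}" for i in range(n_stable)]
    decoys = [f"DEC{i + 1:02d}" for i in range(design.n_reference_decoys)]
    targets = [f"TGT{i + 1:02d}" for i in range(design.n_qpcr_targets)]

    rows = []
    samples = []
    for cultivation in ("field", "glasshouse"):
        for cultivar in design.cultivars:
            for treatment in ("control", "drought"):
                samples.append((f"{cultivation[:2]}_{cultivar}_{treatment}", cultivation,
                                cultivar, treatment))

    base_ct = {g: rng.uniform(18.0, 24.0) for g in stable + decoys}
    decoy_defect = {}
    for i, g in enumerate(decoys):
        decoy_defect[g] = "treatment_shift" if i % 2 == 0 else "cultivar_shift"
    cultivar_shift = {
        g: dict(zip(design.cultivars, rng.normal(0.0, 1.0, size=design.n_cultivars)))
        for g in decoys
        if decoy_defect[g] == "cultivar_shift"
    }
    # planted target expression: informative targets follow the tolerance class
    target_mu = {}
    n_inf_targets = min(len(targets), design.n_informative_transcripts)
    expr_records = {}
    for sample, cultivation, cultivar, treatment in samples:
        for g in stable:
            ct = base_ct[g] + rng.normal(0.0, design.reference_ct_noise)
            rows.append((sample, g, ct, True, cultivation, cultivar, treatment))
        for g in decoys:
            ct = base_ct[g] + rng.normal(0.0, design.reference_ct_noise)
            if decoy_defect[g] == "treatment_shift" and treatment == "drought":
                ct += 2.0
            elif decoy_defect[g] == "cultivar_shift":
                ct += cultivar_shift[g][cultivar]
            rows.append((sample, g, ct, False, cultivation, cultivar, treatment))
        ref_mean = np.mean([r[2] for r in rows[-(len(stable) + len(decoys)):][: len(stable)]])
        for j, g in enumerate(targets):
            mu = target_mu.setdefault(g, rng.uniform(-1.0, 0.5))
            log10_expr = mu + rng.normal(0.0, 0.2)
            if j < n_inf_targets:
                log10_expr += 0.3 * _CLASS_SHIFT[truth.true_class[cultivar]]
            ct = ref_mean - log10_expr / np.log10(2.0) + rng.normal(0.0, design.target_ct_noise)
            # record what normalization against the *planted* reference means
            expr_records[(sample, g)] = log10_expr
            rows.append((sample, g, ct, False, cultivation, cultivar, treatment))

    qpcr = pd.DataFrame(
        rows,
        columns=["sample", "gene", "ct", "is_reference", "cultivation", "cultivar", "treatment"],
    )
    truth.reference_genes = stable
    truth.decoy_genes = decoy_defect
    expr = pd.Series(expr_records).unstack()
    expr.index.name = "sample"
    truth.target_expression = expr
    return qpcr


@dataclasses.dataclass
class SimulatedDataset:
    """Bundle of all simulated inputs plus the ground truth."""

    design: SimulationDesign
    yields: pd.DataFrame
    metabolites: FeatureMatrix
    transcripts: FeatureMatrix
    qpcr: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.yields.to_csv(out / "yields.tsv", sep="\t", index=False)
        self.metabolites.to_tsv(out / "metabolites.tsv")
        self.transcripts.to_tsv(out / "transcripts.tsv")
        self.qpcr.to_csv(out / "qpcr.tsv", sep="\t", index=False)
        self.truth.to_json(out / "ground_truth.json")


def simulate_dataset(design: SimulationDesign, seed: int = 0) -> SimulatedDataset:
    """Generate the full input bundle from one master seed."""
    ss = np.random.SeedSequence(seed)
    s_yield, s_met, s_tr, s_qpcr = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    yields, truth = simulate_yields(design, seed=s_yield)
    metabolites = simulate_features(design, truth, block="metabolite", seed=s_met)
    transcripts = simulate_features(design, truth, block="transcript", seed=s_tr)
    qpcr = simulate_qpcr(design, truth, seed=s_qpcr)
    return SimulatedDataset(
        design=design,
        yields=yields,
        metabolites=metabolites,
        transcripts=transcripts,
        qpcr=qpcr,
        truth=truth,
    )
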