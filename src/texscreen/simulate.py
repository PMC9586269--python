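"""Negative-binomial count simulator with tissue-exclusive spike-ins.

Emulates a four-library hind-leg/front-leg aphid expression design: a
genome-scale background of genes expressed at similar levels in every
library, plus small "spiked" gene sets expressed exclusively (or nearly
exclusively) in one target library. Spike sets default to the pathway
structure of the motivating study — 8 mevalonate-pathway genes, 6 iridoid-
pathway genes and 7 mitochondrial transporters, all private to the hind
legs of sexual females (library ``f-hl``).

Counts for gene g in library j are drawn from a negative binomial with
mean mu(g, j) = rpkm(g, j) * L(g) * N(j) / 1e9 and a common size
(dispersion) parameter, so that simulated counts normalize back to the
intended RPKM level in expectation. Truly exclusive spikes are written as
exact zeros off-target; "leaky" spikes receive a small off-target mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, ParameterError

# Neutral annotation vocabulary for background genes. Deliberately free of
# enzyme-class keywords so that class counts over spiked candidates are
# exact in the default fixture.
BACKGROUND_ANNOTATIONS = (
    "hypothetical protein",
    "uncharacterized protein",
    "zinc finger protein",
    "ribosomal protein L22",
    "cuticle protein precursor",
    "histone H2A",
    "actin-related protein",
    "elongation factor 1-alpha",
    "heat shock protein 70",
    "tubulin beta chain",
)

TRUTH_TARGET_EXCLUSIVE = "target_exclusive"
TRUTH_LEAKY = "leaky"
TRUTH_BACKGROUND = "background"


@dataclass(frozen=True)
class SpikeSet:
    """A named set of genes planted with a known target-tissue pattern."""

    name: str
    n_genes: int
    target_rpkm_mean: float
    annotation_template: str | Sequence[str] = "hypothetical protein"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError(f"spike set {self.name!r}: n_genes must be >= 1")
        if self.target_rpkm_mean <= 0:
            raise ParameterError(f"spike set {self.name!r}: target_rpkm_mean must be > 0")

    def annotations(self) -> list[str]:
        tpl = self.annotation_template
        if isinstance(tpl, str):
            return [tpl] * self.n_genes
        return [tpl[i % len(tpl)] for i in range(self.n_genes)]


def default_spike_sets() -> list[SpikeSet]:
    """The study-design spike structure: mevalonate, iridoid, transporter.

    Annotations mirror the enzyme classes of the genes the study's screen
    surfaced, so the downstream keyword triage has realistic text to chew on.
    """
    return [
        SpikeSet(
            name="mevalonate",
            n_genes=8,
            target_rpkm_mean=200.0,
            annotation_template=(
                "acetyl-CoA acetyltransferase",
                "hydroxymethylglutaryl-CoA synthase",
                "hydroxymethylglutaryl-CoA reductase",
                "mevalonate kinase",
                "phosphomevalonate kinase",
                "diphosphomevalonate decarboxylase",
                "isopentenyl-diphosphate delta-isomerase",
                "farnesyl diphosphate synthase",
            ),
        ),
        SpikeSet(
            name="iridoid",
            n_genes=6,
            target_rpkm_mean=150.0,
            annotation_template=(
                "isoprenyl diphosphate synthase",
                "dolichyldiphosphatase",
                "cytochrome P450 family monooxygenase",
                "NADPH--cytochrome P450 reductase",
                "farnesol dehydrogenase",
                "glucose-methanol-choline oxidase",
            ),
        ),
        SpikeSet(
            name="transporter",
            n_genes=7,
            target_rpkm_mean=100.0,
            annotation_template=(
                "mitochondrial inner membrane transporter",
                "mitochondrial outer membrane transporter",
                "ADP/ATP carrier transporter",
            ),
        ),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults reproduce the motivating four-library design: one library per
    condition, 20,918 gene models, and 21 spiked genes private to ``f-hl``.
    """

    n_genes: int = 20_918
    sample_labels: tuple[str, ...] = ("f-hl", "f-fl", "af-hl", "m-hl")
    target_label: str = "f-hl"
    replicates_per_sample: int = 1
    library_size_mean: float = 2e7
    library_size_cv: float = 0.10
    nb_dispersion: float = 5.0
    baseline_logmean_range: tuple[float, float] = (-2.0, 2.0)  # log10 RPKM
    gene_length_range: tuple[int, int] = (300, 10_000)
    spike_sets: tuple[SpikeSet, ...] = field(
        default_factory=lambda: tuple(default_spike_sets())
    )
    leaky_fraction: float = 0.0
    leaky_level: float = 0.10  # off-target mean as a fraction of target mean
    spike_rpkm_cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        if len(set(self.sample_labels)) != len(self.sample_labels):
            raise ParameterError("sample_labels must be unique")
        n_target = sum(1 for s in self.sample_labels if s == self.target_label)
        if n_target != 1:
            raise ParameterError(
                f"exactly one sample label must be the target; "
                f"{self.target_label!r} matches {n_target} of {self.sample_labels}"
            )
        if len(self.sample_labels) < 2:
            raise ParameterError("need at least two sample labels (target + contrast)")
        if self.replicates_per_sample < 1:
            raise ParameterError("replicates_per_sample must be positive")
        if self.library_size_mean <= 0:
            raise ParameterError("library_size_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ParameterError(f"nb_dispersion must be positive, got {self.nb_dispersion}")
        for name, (lo, hi) in (
            ("baseline_logmean_range", self.baseline_logmean_range),
            ("gene_length_range", self.gene_length_range),
        ):
            if lo > hi:
                raise ParameterError(f"{name} bounds out of order: ({lo}, {hi})")
        if self.gene_length_range[0] < 1:
            raise ParameterError("gene lengths must be >= 1 bp")
        if not 0.0 <= self.leaky_fraction <= 1.0:
            raise ParameterError("leaky_fraction must lie in [0, 1]")
        if self.n_spiked > self.n_genes:
            raise ParameterError(
                f"n_genes={self.n_genes} smaller than total spiked genes ({self.n_spiked})"
            )

    @property
    def n_spiked(self) -> int:
        return sum(s.n_genes for s in self.spike_sets)

    def library_names(self) -> list[str]:
        if self.replicates_per_sample == 1:
            return list(self.sample_labels)
        return [
            f"{label}-r{i + 1}"
            for label in self.sample_labels
            for i in range(self.replicates_per_sample)
        ]

    def library_labels(self) -> list[str]:
        return [
            label
            for label in self.sample_labels
            for _ in range(self.replicates_per_sample)
        ]

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """NB counts with given mean and size k (variance mean + mean^2/k)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def simulate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame, pd.Series]:
    """Draw a synthetic count matrix with ground-truth labels.

    Returns ``(count_matrix, gene_table, truth)`` where ``truth`` maps each
    gene_id to one of ``target_exclusive`` / ``leaky`` / ``background``.
    The same (config, seed) always yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n = config.n_genes
    libraries = config.library_names()
    labels = config.library_labels()
    is_target = np.array([lab == config.target_label for lab in labels])
    n_libs = len(libraries)

    width = max(5, len(str(n)))
    gene_ids = np.array([f"gene_{i + 1:0{width}d}" for i in range(n)])
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )

    # sequencing depth varies log-normally around the configured mean
    sigma2 = np.log1p(config.library_size_cv**2)
    mu_ln = np.log(config.library_size_mean) - sigma2 / 2.0
    lib_sizes = rng.lognormal(mean=mu_ln, sigma=np.sqrt(sigma2), size=n_libs)

    # assign spiked genes to random positions in the gene list
    spike_idx = rng.choice(n, size=config.n_spiked, replace=False)
    n_leaky = int(round(config.leaky_fraction * config.n_spiked))
    leaky_idx = set(
        rng.choice(spike_idx, size=n_leaky, replace=False) if n_leaky else []
    )

    # intended RPKM per gene per library
    lo, hi = config.baseline_logmean_range
    rpkm_intended = np.tile(
        10.0 ** rng.uniform(lo, hi, size=n)[:, None], (1, n_libs)
    )
    annotations = np.array(
        [BACKGROUND_ANNOTATIONS[i] for i in rng.integers(0, len(BACKGROUND_ANNOTATIONS), n)],
        dtype=object,
    )
    truth = np.full(n, TRUTH_BACKGROUND, dtype=object)
    spike_set_name = np.full(n, "", dtype=object)

    cursor = 0
    for spike in config.spike_sets:
        idx = spike_idx[cursor : cursor + spike.n_genes]
        cursor += spike.n_genes
        target_rpkm = spike.target_rpkm_mean * rng.lognormal(
            mean=-np.log1p(config.spike_rpkm_cv**2) / 2.0,
            sigma=np.sqrt(np.log1p(config.spike_rpkm_cv**2)),
            size=spike.n_genes,
        )
        ann = spike.annotations()
        for k, g in enumerate(idx):
            rpkm_intended[g, :] = 0.0
            rpkm_intended[g, is_target] = target_rpkm[k]
            if g in leaky_idx:
                rpkm_intended[g, ~is_target] = config.leaky_level * target_rpkm[k]
                truth[g] = TRUTH_LEAKY
            else:
                truth[g] = TRUTH_TARGET_EXCLUSIVE
            annotations[g] = ann[k]
            spike_set_name[g] = spike.name

    mean_counts = rpkm_intended * lengths[:, None] * lib_sizes[None, :] / 1e9
    counts = _nb_draw(rng, mean_counts, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=libraries)
    counts_df.index.name = "gene_id"
    samples = pd.DataFrame(
        {"label": labels, "is_target": is_target},
        index=pd.Index(libraries, name="library"),
    )
    gene_table = pd.DataFrame(
        {
            "length_bp": lengths.astype(np.int64),
            "annotation": annotations,
            "spike_set": spike_set_name,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth_series = pd.Series(truth, index=gene_ids, name="truth")
    truth_series.index.name = "gene_id"
    return CountMatrix(counts=counts_df, samples=samples), gene_table, truth_series


def write_fixture(
    bundle: tuple[CountMatrix, pd.DataFrame, pd.Series], directory: str | Path
) -> dict[str, Path]:
    """Write counts.tsv / genes.tsv / samples.tsv / truth.tsv for a bundle."""
    cm, gene_table, truth = bundle
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "genes": directory / "genes.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.tsv",
    }
    cm.counts.to_csv(paths["counts"], sep="\t")
    gene_table[["length_bp", "annotation"]].to_csv(paths["genes"], sep="\t")
    samples_out = cm.samples.copy()
    samples_out["is_target"] = samples_out["is_target"].astype(int)
    samples_out.to_csv(paths["samples"], sep="\t")
    truth.to_frame().to_csv(paths["truth"], sep="\t")
    return paths


def read_truth(path: str | Path) -> pd.Series:
    """Load truth.tsv back into a gene_id -> label Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "truth"} <= set(df.columns):
        from .core import SchemaError

        raise SchemaError(f"{path}: expected columns gene_id, truth")
    s = df.set_index("gene_id")["truth"]
    s.index.name = "gene_id"
    return s
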