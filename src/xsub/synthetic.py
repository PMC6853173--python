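"""Synthetic cohorts, mouse profiles, orthology tables and GEMM fixtures.

The generator emulates the statistical structure the downstream analysis
assumes, directly on the log-expression scale:

* a human-like cohort in which each molecular subtype up-regulates a
  disjoint block of genes on top of Gaussian noise, with optional additive
  batch effects and censored survival whose hazard is tied to a block score;
* mouse-model differential-expression profiles whose up-regulated genes
  overlap a chosen subtype's block at a configurable fraction;
* human-mouse orthology tables with a controlled fraction of one-to-many
  mappings;
* a packaged genetically-engineered-mouse (GEMM) incidence table for the
  metastatic KPN genotype (KrasG12D; Trp53-null; Notch1-ICD).

All randomness flows from a single integer seed per config; identical
configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xsub.errors import ConfigError, XsubError

__all__ = [
    "CohortSimConfig",
    "MouseSimConfig",
    "simulate_cohort",
    "simulate_mouse_profiles",
    "simulate_orthology",
    "kpn_incidence_fixture",
    "write_gemm_csv",
    "read_gemm_csv",
]

GENOTYPES = ("PN", "AP", "APN", "KP", "KPN")
METASTATIC_SITES = ("liver", "lung", "lymph-node", "diaphragm", "peritoneum")


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the synthetic human-like cohort.

    The last subtype label is the poor-prognosis analogue: its block score
    drives the survival hazard (log-hazard = ``hazard_beta`` x standardized
    block score), mirroring a mesenchymal-like subtype carrying the worst
    outcome.
    """

    n_samples: int = 500
    n_genes: int = 2000
    subtype_labels: tuple[str, ...] = ("CMS1", "CMS2", "CMS3", "CMS4")
    genes_per_subtype_block: int = 150
    block_effect: float = 1.5
    noise_sd: float = 1.0
    n_batches: int = 0
    batch_effect_sd: float = 0.0
    hazard_beta: float = 0.8
    censor_time: float = 1825.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if len(self.subtype_labels) < 2:
            raise ConfigError("need >= 2 subtype labels")
        if len(set(self.subtype_labels)) != len(self.subtype_labels):
            raise ConfigError("subtype labels must be unique")
        if self.genes_per_subtype_block < 1:
            raise ConfigError("genes_per_subtype_block must be >= 1")
        if self.genes_per_subtype_block * len(self.subtype_labels) > self.n_genes:
            raise ConfigError(
                f"block genes ({self.genes_per_subtype_block} x {len(self.subtype_labels)}) "
                f"exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_batches < 0:
            raise ConfigError("n_batches must be >= 0")
        if self.batch_effect_sd < 0:
            raise ConfigError("batch_effect_sd must be >= 0")
        if self.censor_time <= 0:
            raise ConfigError(f"censor_time must be > 0, got {self.censor_time}")

    @property
    def genes(self) -> list[str]:
        return [f"g{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def samples(self) -> list[str]:
        return [f"s{i:04d}" for i in range(1, self.n_samples + 1)]

    def blocks(self) -> dict[str, list[str]]:
        """Disjoint up-regulated gene block per subtype (deterministic layout)."""
        genes = self.genes
        k = self.genes_per_subtype_block
        return {
            label: genes[i * k : (i + 1) * k]
            for i, label in enumerate(self.subtype_labels)
        }

    @property
    def risk_subtype(self) -> str:
        return self.subtype_labels[-1]


@dataclass(frozen=True)
class MouseSimConfig:
    """Parameters of a simulated mouse-model DE profile.

    ``overlap_fraction`` of the target subtype's block genes are planted as
    up-regulated in the mouse profile; the remaining up-regulated genes are
    decoys drawn from outside every subtype block.
    """

    target_subtype: str = "CMS4"
    overlap_fraction: float = 1.0
    lfc_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ConfigError(
                f"overlap_fraction must be in [0, 1], got {self.overlap_fraction}"
            )
        if self.lfc_scale <= 0:
            raise ConfigError(f"lfc_scale must be > 0, got {self.lfc_scale}")


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a log-expression matrix and matching clinical table.

    Expression: per-gene baseline ~ N(7, 1) plus N(0, noise_sd) noise;
    subtype-block genes gain ``block_effect`` in that subtype's samples;
    per-(gene, batch) offsets ~ N(0, batch_effect_sd) when batches are on.
    Survival: exponential with rate lambda0 * exp(hazard_beta * z), z the
    cohort-standardized mean expression of the risk-subtype block, with
    lambda0 set so the median baseline survival is censor_time / 2;
    administrative censoring at ``censor_time``.
    """
    rng = np.random.default_rng(config.seed)
    genes, samples = config.genes, config.samples
    labels = np.array(config.subtype_labels)
    subtype = rng.choice(labels, size=config.n_samples)

    baseline = rng.normal(7.0, 1.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_samples)
    )

    blocks = config.blocks()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for label, block in blocks.items():
        cols = np.flatnonzero(subtype == label)
        rows = np.array([gene_pos[g] for g in block])
        values[np.ix_(rows, cols)] += config.block_effect

    batch = None
    if config.n_batches > 0:
        batch = np.array(
            [f"batch{(i % config.n_batches) + 1}" for i in range(config.n_samples)]
        )
        offsets = rng.normal(
            0.0, config.batch_effect_sd, size=(config.n_genes, config.n_batches)
        )
        for b in range(config.n_batches):
            cols = np.flatnonzero(batch == f"batch{b + 1}")
            values[:, cols] += offsets[:, [b]]

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)

    risk_rows = [gene_pos[g] for g in blocks[config.risk_subtype]]
    raw_score = values[risk_rows].mean(axis=0)
    z = (raw_score - raw_score.mean()) / raw_score.std(ddof=1)
    lambda0 = np.log(2.0) / (config.censor_time / 2.0)
    rate = lambda0 * np.exp(config.hazard_beta * z)
    latent = rng.exponential(1.0 / rate)
    time = np.minimum(latent, config.censor_time)
    event = latent <= config.censor_time

    clin = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "cms": subtype,
            "cris": pd.array([pd.NA] * config.n_samples),
            "batch": batch if batch is not None else pd.array([pd.NA] * config.n_samples),
        },
        index=pd.Index(samples, name="sample"),
    )
    return expr, clin


def simulate_mouse_profiles(
    config: MouseSimConfig,
    cohort_blocks: dict[str, list[str]],
    gene_universe: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a mouse-model DE table whose up-regulation overlaps a subtype block.

    ``round(overlap_fraction x block size)`` genes of the target block are
    planted with strong positive logFC and tiny adjusted p; the rest of the
    "up" set are decoy genes outside every block.  All genes of
    ``gene_universe`` (default: the union of the blocks) appear in the table,
    background genes with null logFC ~ N(0, 0.3 x lfc_scale) and uniform p.
    Gene ids stay in the cohort (human) namespace; translate through an
    orthology index to obtain mouse ids.
    """
    if config.target_subtype not in cohort_blocks:
        raise KeyError(
            f"simulate_mouse_profiles: unknown subtype {config.target_subtype!r}; "
            f"known: {sorted(cohort_blocks)}"
        )
    rng = np.random.default_rng(config.seed)
    block = list(cohort_blocks[config.target_subtype])
    all_block_genes = {g for genes in cohort_blocks.values() for g in genes}
    if gene_universe is None:
        universe = sorted(all_block_genes)
    else:
        universe = list(gene_universe)
        if not all_block_genes <= set(universe):
            raise XsubError("simulate_mouse_profiles: gene_universe must contain all block genes")

    n_planted = round(config.overlap_fraction * len(block))
    planted = list(rng.choice(block, size=n_planted, replace=False))
    off_block = [g for g in universe if g not in all_block_genes]
    n_decoys = len(block) - n_planted
    if n_decoys > len(off_block):
        raise XsubError(
            f"simulate_mouse_profiles: need {n_decoys} decoy genes outside the blocks, "
            f"only {len(off_block)} available in the universe"
        )
    decoys = list(rng.choice(off_block, size=n_decoys, replace=False)) if n_decoys else []
    up = set(planted) | set(decoys)

    lfc = rng.normal(0.0, 0.3 * config.lfc_scale, size=len(universe))
    p = rng.uniform(0.0, 1.0, size=len(universe))
    de = pd.DataFrame(
        {"log_fc": lfc, "p_value": p, "p_adj": np.minimum(p * 2.0, 1.0)},
        index=pd.Index(universe, name="gene"),
    )
    up_idx = [g for g in universe if g in up]
    de.loc[up_idx, "log_fc"] = config.lfc_scale * (
        1.5 + np.abs(rng.normal(0.0, 0.5, size=len(up_idx)))
    )
    tiny = rng.uniform(1e-12, 1e-8, size=len(up_idx))
    de.loc[up_idx, "p_value"] = tiny
    de.loc[up_idx, "p_adj"] = tiny * 10.0
    return de


def simulate_orthology(
    n_pairs: int,
    frac_one_to_many: float,
    seed: int = 0,
    human_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a human-mouse orthology table.

    Every human gene gets one primary mouse partner; exactly
    ``round(frac_one_to_many x n_pairs)`` human genes get a second partner
    with a strictly lower homology percentage, exercising the
    highest-homology resolution rule.
    """
    if not 0.0 <= frac_one_to_many < 1.0:
        raise ConfigError(
            f"frac_one_to_many must be in [0, 1), got {frac_one_to_many}"
        )
    if n_pairs < 1:
        raise ConfigError(f"n_pairs must be >= 1, got {n_pairs}")
    rng = np.random.default_rng(seed)
    if human_genes is None:
        human = [f"h{i:05d}" for i in range(1, n_pairs + 1)]
    else:
        if len(human_genes) != n_pairs:
            raise ConfigError("human_genes length must equal n_pairs")
        human = list(human_genes)

    primary_hom = rng.uniform(80.0, 100.0, size=n_pairs)
    rows = [
        (h, f"m_{h}", round(float(hom), 4)) for h, hom in zip(human, primary_hom)
    ]
    n_multi = round(frac_one_to_many * n_pairs)
    multi = rng.choice(n_pairs, size=n_multi, replace=False)
    extra_drop = rng.uniform(5.0, 20.0, size=n_multi)
    for idx, drop in zip(multi, extra_drop):
        h = human[idx]
        hom = max(round(float(primary_hom[idx] - drop), 4), 0.0)
        rows.append((h, f"m_{h}_alt", hom))
    return pd.DataFrame(rows, columns=["human_gene", "mouse_gene", "homology_pct"])


def kpn_incidence_fixture() -> pd.DataFrame:
    """Packaged 29-animal KPN metastasis-incidence table.

    Liver-metastasis incidence is 24/29 (83%) and every animal carries at
    least one metastatic site (fully penetrant metastasis).  The liver counts
    are the anchored quantities; the non-liver site assignments and survival
    days are synthetic placeholders laid out deterministically so the table
    exercises the incidence-summary code path.
    """
    rows = []
    for i in range(1, 30):
        sites = {"liver"} if i <= 24 else {"lymph-node"}
        if i % 5 == 0:
            sites.add("lung")  # synthetic placeholder co-occurrence
        rows.append(
            {
                "animal_id": f"KPN{i:02d}",
                "genotype": "KPN",
                "survival_days": 150 + 5 * i,
                "event": True,
                "sites": frozenset(sites),
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")


def write_gemm_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["sites"] = [";".join(sorted(s)) for s in out["sites"]]
    out["event"] = out["event"].astype(int)
    out.to_csv(path, index_label="animal_id")


def read_gemm_csv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, index_col="animal_id", keep_default_na=False)
    if (pd.to_numeric(cohort["survival_days"], errors="coerce") <= 0).any():
        raise XsubError(f"{path}: survival_days must be > 0")
    unknown = set(cohort["genotype"]) - set(GENOTYPES)
    if unknown:
        raise XsubError(f"{path}: unknown genotype label(s) {sorted(unknown)}")
    cohort["event"] = cohort["event"].astype(bool)
    cohort["sites"] = [
        frozenset(s for s in str(raw).split(";") if s) for raw in cohort["sites"]
    ]
    bad_sites = {s for sites in cohort["sites"] for s in sites} - set(METASTATIC_SITES)
    if bad_sites:
        raise XsubError(f"{path}: unknown metastatic site(s) {sorted(bad_sites)}")
    return cohort
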