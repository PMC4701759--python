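"""Synthetic proteome and peptide-evidence generation.

The generator emulates the statistical structure the abundance analysis
assumes: a proteome whose true abundances are log-normal, detection across
K = 4 MS data sets where the expected unique-peptide count grows with both
abundance and protein size (lambda_{i,d} = alpha * A_i * (L_i / Lbar)^gamma
* dataset effect), 95%-confidence flags on peptide rows, and homolog groups
spanning multiple genome variants.  A truth table is emitted alongside so
recovery of abundance ranks and of the mass exponent gamma can be measured.

Randomness: each operation draws from its own numpy Generator seeded from
(config seed, operation name), so stages are individually reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digest import peptide_set
from .io import EvidenceTable, PeptideEvidence, ProteinRecord

#: residue background (uniform over the 20 standard residues)
_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_DEFAULT_CLASS_PROBS = {
    "HEAD": 0.17, "BP": 0.08, "TAIL": 0.08, "REC": 0.06, "REP": 0.04,
    "MOD": 0.06, "VIR": 0.17, "UK": 0.34,
}

#: genome name -> locus-tag prefix for generated proteins; variants of one
#: base protein share the tag number across prefixes
_GENOME_NAMES = ("wStr", "wMel", "wPip")
_GENOME_PREFIX = {"wStr": "WS", "wMel": "WM", "wPip": "WQ"}


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions being emulated."""

    n_proteins: int = 500
    k_datasets: int = 4
    dataset_ids: tuple[str, ...] | None = None  # default D, E, F, G, ...
    median_length: float = 300.0       # aa; log-normal median
    sigma_log_length: float = 0.4      # sd of ln(length)
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROBS))
    mu_log_abundance: float = 0.0      # mean of log10 A
    sigma_log_abundance: float = 0.6   # sd of log10 A
    alpha: float = 4.0                 # expected peptides per data set at A=1, L=Lbar
    gamma: float = 0.7                 # mass exponent of the detection rate
    dataset_effects: tuple[float, ...] | None = None  # default all 1.0
    low_conf_fraction: float = 0.05    # fraction of rows flagged below 95% confidence
    homolog_fraction: float = 0.1      # proteins duplicated into 2-3 genome variants
    substitution_rate: float = 0.05    # per-site substitution rate for variants
    digest_min_len: int = 6
    digest_max_missed: int = 1
    seed: int = 0

    def resolved_dataset_ids(self) -> list[str]:
        if self.dataset_ids is not None:
            return list(self.dataset_ids)
        return [chr(ord("D") + i) for i in range(self.k_datasets)]

    def resolved_dataset_effects(self) -> np.ndarray:
        if self.dataset_effects is None:
            return np.ones(self.k_datasets)
        return np.asarray(self.dataset_effects, dtype=float)

    def validate(self) -> None:
        problems = []
        if self.n_proteins < 0:
            problems.append("n_proteins must be >= 0")
        if self.k_datasets < 1:
            problems.append("k_datasets must be >= 1")
        if self.dataset_ids is not None and len(self.dataset_ids) != self.k_datasets:
            problems.append("dataset_ids length must equal k_datasets")
        for name in ("median_length", "sigma_log_length", "sigma_log_abundance",
                     "alpha", "gamma"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            problems.append("class_probs must sum to 1")
        if any(p < 0 for p in self.class_probs.values()):
            problems.append("class_probs must be non-negative")
        if not 0.0 <= self.low_conf_fraction <= 1.0:
            problems.append("low_conf_fraction must be in [0, 1]")
        if not 0.0 <= self.homolog_fraction <= 1.0:
            problems.append("homolog_fraction must be in [0, 1]")
        if not 0.0 <= self.substitution_rate <= 1.0:
            problems.append("substitution_rate must be in [0, 1]")
        if len(self.resolved_dataset_effects()) != self.k_datasets:
            problems.append("dataset_effects length must equal k_datasets")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


def _rng(config: SimConfig, operation: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(operation.encode())])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    seq = rng.choice(_ALPHABET, size=length)
    # guarantee ceil(L/15) tryptic sites so every protein yields peptides
    needed = -(-length // 15)
    kr = np.isin(seq, ("K", "R")).sum()
    if kr < needed:
        # avoid the final residue: a C-terminal K/R adds no internal site
        positions = rng.choice(max(length - 1, 1), size=needed, replace=False)
        seq[positions] = rng.choice(("K", "R"), size=needed)
    return "".join(seq)


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    seq = np.array(list(sequence))
    hits = rng.random(len(seq)) < rate
    if hits.any():
        seq[hits] = rng.choice(_ALPHABET, size=int(hits.sum()))
    return "".join(seq)


def generate_proteome(config: SimConfig
                      ) -> tuple[list[ProteinRecord], pd.DataFrame, pd.DataFrame]:
    """Generate (protein records, annotation table, truth table).

    Lengths are log-normal (median ``median_length``); classes are drawn from
    ``class_probs``; a ``homolog_fraction`` of base proteins is duplicated
    into 2–3 genome variants by point substitutions at ``substitution_rate``
    (length-preserving), sharing a homolog group.  The truth table records
    the true abundance A_i, length, class, group and per-data-set expected
    count lambda for every protein (variants share their base's abundance).
    """
    config.validate()
    rng = _rng(config, "generate_proteome")
    n = config.n_proteins
    dataset_ids = config.resolved_dataset_ids()
    effects = config.resolved_dataset_effects()

    lengths = np.maximum(
        30,
        np.round(rng.lognormal(np.log(config.median_length),
                               config.sigma_log_length, size=n)).astype(int),
    )
    classes = rng.choice(list(config.class_probs), size=n,
                         p=list(config.class_probs.values()))
    log_a = rng.normal(config.mu_log_abundance, config.sigma_log_abundance, size=n)

    records: list[ProteinRecord] = []
    truth_rows = []
    mean_len = float(lengths.mean()) if n else 1.0
    for i in range(n):
        locus = f"WS{i + 1:04d}"
        seq = _random_sequence(rng, int(lengths[i]))
        abundance = 10.0 ** log_a[i]
        group = ""
        variants = [(locus, seq, _GENOME_NAMES[0])]
        if rng.random() < config.homolog_fraction:
            group = f"grp{i + 1:04d}"
            for v in range(int(rng.integers(1, 3))):  # 1 or 2 extra variants
                genome = _GENOME_NAMES[v + 1]
                vseq = _mutate(rng, seq, config.substitution_rate)
                variants.append((f"{_GENOME_PREFIX[genome]}{i + 1:04d}", vseq,
                                 genome))
        for tag, vseq, genome in variants:
            records.append(ProteinRecord(
                locus_tag=tag, sequence=vseq, genome=genome,
                homolog_group=group, functional_class=str(classes[i]),
            ))
            lam = (config.alpha * abundance
                   * (len(vseq) / mean_len) ** config.gamma * effects)
            row = {
                "locus_tag": tag, "base_locus": locus, "genome": genome,
                "true_abundance": abundance, "log10_abundance": log_a[i],
                "length": len(vseq), "functional_class": str(classes[i]),
                "homolog_group": group,
            }
            row.update({f"lambda_{d}": lam[k] for k, d in enumerate(dataset_ids)})
            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    annotation = pd.DataFrame({
        "locus_tag": [r.locus_tag for r in records],
        "class": [r.functional_class for r in records],
        "region": "",
        "group": [r.homolog_group for r in records],
        "kda": [round(r.mass_kda, 3) for r in records],
    })
    return records, annotation, truth


def simulate_detection(proteome: list[ProteinRecord], truth: pd.DataFrame,
                       config: SimConfig) -> EvidenceTable:
    """Draw peptide evidence from the detection model.

    Per (protein, data set) the unique-peptide count is Poisson(lambda)
    capped at the size of the protein's theoretical tryptic peptide set
    (length >= 6, <= 1 missed cleavage); that many distinct peptides are
    sampled without replacement.  Rows get confidence 0.99 except a
    ``low_conf_fraction`` assigned 0.5 (below the 95% counting threshold).
    """
    config.validate()
    rng = _rng(config, "simulate_detection")
    dataset_ids = config.resolved_dataset_ids()
    lam_cols = [f"lambda_{d}" for d in dataset_ids]
    lam_by_locus = truth.set_index("locus_tag")[lam_cols] if len(truth) else None

    rows: list[PeptideEvidence] = []
    for rec in proteome:
        peptides = sorted(peptide_set(rec.sequence, config.digest_min_len,
                                      config.digest_max_missed))
        if not peptides:
            warnings.warn(f"{rec.locus_tag}: empty tryptic digest, no detections")
            continue
        lams = lam_by_locus.loc[rec.locus_tag].to_numpy(dtype=float)
        for k, ds in enumerate(dataset_ids):
            count = min(int(rng.poisson(lams[k])), len(peptides))
            if count == 0:
                continue
            chosen = rng.choice(len(peptides), size=count, replace=False)
            for idx in sorted(chosen):
                conf = 0.5 if rng.random() < config.low_conf_fraction else 0.99
                rows.append(PeptideEvidence(
                    peptide=peptides[idx], dataset_id=ds,
                    matched_proteins={rec.locus_tag}, confidence=conf,
                ))
    return EvidenceTable(rows=rows, dataset_ids=dataset_ids)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
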