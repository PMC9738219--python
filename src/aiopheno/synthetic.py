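"""Synthetic genotype / climate / phenotype generator.

Emulates the statistical structure the pipeline assumes so every stage is
testable without external data: a structured germplasm panel (default 1775
accessions in 5 subpopulations, 500 SNPs), 6 planting environments with
daily climate series, and a days-to-flowering phenotype in [25, 120] driven
by a handful of causal SNPs, climate-window summaries, and G×E interaction
terms plus Gaussian noise.

Subpopulation structure follows a Balding–Nichols-style divergence model:
an ancestral allele frequency p per SNP, subpopulation frequencies drawn
from Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence F, dosages
Binomial(2, p_s). Climate effects enter through window summaries (mean
maximum temperature, total precipitation, mean day length) so the climate
block of the AIO carries learnable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ClimateWindow, GenotypeMatrix, PhenotypeTable, CLIMATE_FACTORS
import pandas as pd


@dataclass
class SimConfig:
    """Study-shape defaults: 1775 accessions, 5 subpopulations, 6
    environments, flowering 25–120 days."""

    n_accessions: int = 1775
    n_snps: int = 500
    n_subpops: int = 5
    divergence: float = 0.1          # Balding–Nichols F
    n_environments: int = 6
    causal_snps: tuple | None = None                     # None → 5 evenly spaced
    effect_sizes: tuple = (4.0, 4.0, -4.0, 4.0, -4.0)   # days per minor allele
    climate_coefs: dict = field(default_factory=lambda: {
        "temp_max_mean": -1.2,       # warmer start → earlier flowering
        "precip_total": 0.05,
        "day_length_mean": 1.5,
    })
    gxe: tuple = ((0, "temp_max_mean", -0.4),)   # (causal slot, summary, days/allele/unit)
    noise_sd: float = 6.0
    baseline_days: float = 70.0
    seed: int = 0

    def __post_init__(self):
        if self.causal_snps is None:
            k = len(self.effect_sizes)
            self.causal_snps = tuple(np.linspace(0, self.n_snps - 1, k + 2)[1:-1].astype(int))
        if len(self.causal_snps) != len(self.effect_sizes):
            raise ValueError("one effect size per causal SNP required")
        if any(j >= self.n_snps for j in self.causal_snps):
            raise ValueError("causal SNP index out of range")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be ≥ 0")


def generate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Structured dosage matrix; returns (GenotypeMatrix, subpop labels)."""
    rng = np.random.default_rng(cfg.seed)
    n, m, P = cfg.n_accessions, cfg.n_snps, cfg.n_subpops
    ancestral = rng.uniform(0.1, 0.9, m)
    F = cfg.divergence
    if F > 0:
        a = ancestral * (1 - F) / F
        b = (1 - ancestral) * (1 - F) / F
        subpop_freq = rng.beta(a, b, size=(P, m))
    else:
        subpop_freq = np.tile(ancestral, (P, 1))
    sizes = np.full(P, n // P)
    sizes[: n % P] += 1
    labels = np.repeat(np.arange(P), sizes)
    values = np.empty((n, m), dtype=np.int64)
    for s in range(P):
        mask = labels == s
        values[mask] = rng.binomial(2, subpop_freq[s], size=(mask.sum(), m))
    ids = [f"ACC{i:05d}" for i in range(n)]
    snp_ids = [f"SNP{j:04d}" for j in range(m)]
    return GenotypeMatrix(values, ids, snp_ids), labels


def generate_climate(cfg: SimConfig, environment: int = 0) -> ClimateWindow:
    """One environment's 25-day window: smooth seasonal day length,
    autocorrelated temperatures with Tn < Tx, zero-inflated precipitation,
    humidity in [0, 100], non-negative solar radiation."""
    rng = np.random.default_rng(cfg.seed * 1009 + 31 * environment + 7)
    days = np.arange(25)
    phase = rng.uniform(0, 2 * np.pi)
    day_length = 12.0 + 2.5 * np.sin(2 * np.pi * (days / 365.0) + phase)
    base_t = rng.uniform(12.0, 28.0)
    tmax = np.empty(25)
    tmax[0] = base_t + rng.normal(0, 1.5)
    for d in range(1, 25):
        tmax[d] = base_t + 0.7 * (tmax[d - 1] - base_t) + rng.normal(0, 1.5)
    spread = rng.uniform(5.0, 10.0)
    tmin = tmax - spread + rng.normal(0, 0.8, 25)
    tmin = np.minimum(tmin, tmax - 0.5)       # construction constraint Tn < Tx
    wet = rng.random(25) < 0.35
    precip = np.where(wet, rng.gamma(2.0, 4.0, 25), 0.0)
    humidity = np.clip(60 + 15 * np.tanh((precip - 2) / 5) + rng.normal(0, 8, 25), 0, 100)
    solar = np.clip(18 + 6 * np.sin(2 * np.pi * days / 365 + phase) + rng.normal(0, 3, 25), 0.1, None)
    return ClimateWindow(np.vstack([day_length, tmin, tmax, precip, humidity, solar]))


def climate_summaries(window: ClimateWindow) -> dict:
    """Window summaries through which climate affects the phenotype."""
    return {
        "temp_max_mean": float(window.factor("temp_max").mean()),
        "precip_total": float(window.factor("precipitation").sum()),
        "day_length_mean": float(window.factor("day_length").mean()),
    }


def generate_phenotype(G: GenotypeMatrix, climates: list[ClimateWindow],
                       cfg: SimConfig) -> PhenotypeTable:
    """days = baseline + Σ SNP effects + Σ climate-summary effects + G×E +
    noise, rounded and clipped to [25, 120]; one record per
    accession × environment."""
    rng = np.random.default_rng(cfg.seed + 9173)
    records = []
    causal = np.asarray(cfg.causal_snps)
    effects = np.asarray(cfg.effect_sizes)
    genetic = G.values[:, causal] @ effects
    for e, window in enumerate(climates):
        summ = climate_summaries(window)
        clim = sum(coef * (summ[name] - _SUMMARY_CENTER[name])
                   for name, coef in cfg.climate_coefs.items())
        gxe = np.zeros(G.n_accessions)
        for slot, name, coef in cfg.gxe:
            gxe += coef * G.values[:, causal[slot]] * (summ[name] - _SUMMARY_CENTER[name])
        days = (cfg.baseline_days + genetic - genetic.mean() + clim + gxe
                + rng.normal(0, cfg.noise_sd, G.n_accessions))
        days = np.clip(np.round(days), 25, 120).astype(int)
        records.append(pd.DataFrame({
            "accession_id": G.accession_ids,
            "environment_id": f"ENV{e}",
            "days_to_flower": days,
        }))
    return PhenotypeTable(pd.concat(records, ignore_index=True))


#: Centers used so climate effects are deviations from a typical window
#: (keeps the baseline interpretable as days under average conditions).
_SUMMARY_CENTER = {"temp_max_mean": 20.0, "precip_total": 25.0, "day_length_mean": 12.0}


def noise_sd_for_heritability(cfg: SimConfig, h2: float) -> float:
    """Noise SD giving narrow-sense heritability ≈ h² for the additive SNP
    part under the configured divergence model (variance computed from a
    large simulated panel)."""
    probe = SimConfig(n_accessions=2000, n_snps=cfg.n_snps, n_subpops=cfg.n_subpops,
                      divergence=cfg.divergence, causal_snps=cfg.causal_snps,
                      effect_sizes=cfg.effect_sizes, seed=cfg.seed)
    G, _ = generate_genotypes(probe)
    genetic = G.values[:, np.asarray(cfg.causal_snps)] @ np.asarray(cfg.effect_sizes)
    var_g = genetic.var()
    if not 0 < h2 < 1:
        raise ValueError("h² must be in (0,1)")
    return float(np.sqrt(var_g * (1 - h2) / h2))


def generate_dataset(cfg: SimConfig):
    """Full simulated study: returns (GenotypeMatrix, subpop labels,
    [ClimateWindow per environment], PhenotypeTable)."""
    G, labels = generate_genotypes(cfg)
    climates = [generate_climate(cfg, e) for e in range(cfg.n_environments)]
    phenotypes = generate_phenotype(G, climates, cfg)
    return G, labels, climates, phenotypes
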