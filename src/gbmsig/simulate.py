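"""Synthetic survival cohorts with a planted prognostic gene signature.

The generator emulates the statistical structure the downstream analysis
assumes: log2-scale per-gene expression (normal, gene-specific mean/SD), a
minority of "signature" genes whose standardized expression shifts the event
hazard through a linear predictor, exponential survival times under
proportional hazards with independent uniform right-censoring, optional
per-batch additive mean shifts, and a GMT collection in which the planted
genes are concentrated in designated "resistance" sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

SUBTYPES = ("classical", "mesenchymal", "neural", "proneural")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-signature survival cohort.

    ``effect_size`` is the standardized hazard shift of the whole planted
    signature: when ``beta_true`` is not given explicitly, every signature
    gene gets the coefficient effect_size / sqrt(n_signature_genes), so the
    linear predictor eta (on standardized expression) has SD equal to
    ``effect_size``. ``baseline_hazard`` is in events/day (default 1/300, giving
    a median time-to-progression of ~200 days at eta = 0, the scale of GBM
    progression-free survival). ``batch_shift`` is the additive mean offset
    between the two extreme batches, in units of each gene's SD.
    """

    n_samples: int = 200
    n_genes: int = 1000
    n_signature_genes: int = 20
    effect_size: float = 1.0
    beta_true: tuple[float, ...] | None = None
    baseline_hazard: float = 1.0 / 300.0
    censoring_rate: float = 0.3
    n_gene_sets: int = 10
    set_size: int = 25
    batch_count: int = 2
    batch_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_gene_sets,
               self.set_size, self.batch_count) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_signature_genes < 0 or self.n_signature_genes > self.n_genes:
            raise ConfigurationError(
                "n_signature_genes must lie in [0, n_genes]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1)")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.beta_true is not None and len(self.beta_true) != self.n_signature_genes:
            raise ConfigurationError(
                "beta_true length must equal n_signature_genes")

    def resolved_betas(self) -> np.ndarray:
        if self.beta_true is not None:
            return np.asarray(self.beta_true, dtype=float)
        k = self.n_signature_genes
        if k == 0:
            return np.zeros(0)
        return np.full(k, self.effect_size / np.sqrt(k), dtype=float)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated cohort: which genes carry signal."""

    signature_gene_ids: list[str]
    beta_true: list[float]
    batch_assignments: list[str]


def _calibrate_censoring_bound(times: np.ndarray, target: float) -> float:
    """Upper bound c of the U(0, c) censoring law hitting the target rate.

    With C ~ U(0, c), P(censored | T = t) = min(t, c)/c, so the expected
    censored fraction over the drawn event times is mean(min(t, c)/c),
    monotone decreasing in c; solve by bisection.
    """
    lo, hi = float(times.min()) * 1e-6, float(times.max()) * 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(np.minimum(times, mid) / mid))
        if frac > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _censor(times: np.ndarray, rate: float, rng: np.random.Generator):
    if rate == 0.0:
        return times.copy(), np.ones_like(times, dtype=int)
    c = _calibrate_censoring_bound(times, rate)
    cens = rng.uniform(0.0, c, size=times.shape)
    observed = np.minimum(times, cens)
    event = (times <= cens).astype(int)
    return observed, event


def simulate_cohort(config: SimulationConfig):
    """Generate (expression, clinical, gene_sets, truth) under the config.

    Expression of non-signature genes is i.i.d. per gene; signature genes feed
    the linear predictor eta = sum(beta * z) on their standardized values, and
    survival times are exponential with hazard baseline_hazard * exp(eta).
    Batches are assigned round-robin over the eta ranking so that batch and
    planted signal are not confounded.
    """
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_samples, config.n_genes, config.n_signature_genes

    gene_ids = [f"G{i + 1:05d}" for i in range(p)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    means = rng.uniform(5.0, 10.0, size=p)
    sds = rng.uniform(0.3, 1.5, size=p)
    z = rng.standard_normal((p, n))

    sig_idx = np.sort(rng.choice(p, size=k, replace=False)) if k else np.array([], dtype=int)
    # prognostic genes are planted among the high-variance genes (they must
    # be discoverable downstream of a variance filter, as in real cohorts
    # where resistance pathways vary across tumours)
    if k:
        sds[sig_idx] = rng.uniform(0.9, 1.5, size=k)
    betas = config.resolved_betas()
    eta = betas @ z[sig_idx] if k else np.zeros(n)

    pfs_true = rng.exponential(1.0 / (config.baseline_hazard * np.exp(eta)))
    os_true = pfs_true + rng.exponential(1.0 / (config.baseline_hazard * np.exp(eta)))
    pfs_days, pfs_event = _censor(pfs_true, config.censoring_rate, rng)
    os_days, os_event = _censor(os_true, config.censoring_rate, rng)

    # balanced batches: round-robin over the eta ranking
    order = np.argsort(eta, kind="stable")
    batch_idx = np.empty(n, dtype=int)
    batch_idx[order] = np.arange(n) % config.batch_count
    batch_labels = np.array([f"B{b + 1}" for b in batch_idx])

    expr = means[:, None] + sds[:, None] * z
    if config.batch_count > 1 and config.batch_shift != 0.0:
        coeff = (batch_idx - (config.batch_count - 1) / 2.0) / (config.batch_count - 1)
        expr = expr + sds[:, None] * (config.batch_shift * coeff)[None, :]

    expr_df = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "pfs_days": pfs_days,
        "pfs_event": pfs_event,
        "os_days": os_days,
        "os_event": os_event,
        "age": np.clip(rng.normal(58.0, 10.0, size=n), 18, 90).round(1),
        "mgmt_methylated": rng.integers(0, 2, size=n),
        "subtype": rng.choice(SUBTYPES, size=n),
        "batch": batch_labels,
        "adjuvant": np.ones(n, dtype=int),
    }).set_index("sample_id", drop=False)

    sig_genes = [gene_ids[i] for i in sig_idx]
    gene_sets = _build_gene_sets(config, gene_ids, sig_genes, sds, rng)
    truth = PlantedTruth(
        signature_gene_ids=sig_genes,
        beta_true=list(map(float, betas)),
        batch_assignments=list(batch_labels),
    )
    return expr_df, clinical, gene_sets, truth


def _build_gene_sets(config: SimulationConfig, gene_ids: list[str],
                     sig_genes: list[str], sds: np.ndarray,
                     rng: np.random.Generator):
    """GMT collection with planted genes concentrated in 'resistance' sets.

    Resistance sets are variance-coherent: their filler genes come from the
    high-variance half of the genome, so that — like real resistance
    pathways in tumour cohorts — they are over-represented among the genes
    that pass a variance filter, while background sets sample all genes.
    """
    n_resistance = max(1, config.n_gene_sets // 2)
    sig_set = set(sig_genes)
    non_sig = [g for g in gene_ids if g not in sig_set]
    # non-signature genes ordered by SD descending; top half = high-variance
    sd_of = dict(zip(gene_ids, sds))
    by_var = sorted(non_sig, key=lambda g: (-sd_of[g], g))
    high_var_pool = by_var[: max(1, len(by_var) // 2)]

    sets: dict[str, list[str]] = {}
    buckets: list[list[str]] = [[] for _ in range(n_resistance)]
    for j, g in enumerate(sig_genes):
        buckets[j % n_resistance].append(g)
    for i in range(config.n_gene_sets):
        if i < n_resistance:
            members = list(buckets[i])
            pool = high_var_pool
            n_fill = max(0, config.set_size - len(members))
            name = f"RESISTANCE_{i + 1:02d}"
        else:
            members = []
            pool = non_sig
            n_fill = config.set_size
            name = f"BACKGROUND_{i - n_resistance + 1:02d}"
        fill = rng.choice(len(pool), size=min(n_fill, len(pool)), replace=False)
        members.extend(pool[j] for j in sorted(fill))
        sets[name] = members
    return sets


def resistance_set_names(gene_sets: dict[str, list[str]]) -> list[str]:
    return [name for name in gene_sets if name.startswith("RESISTANCE_")]


def simulate_two_class(n_per_class: int, n_genes: int, n_informative: int,
                       effect_size: float, seed: int):
    """Two-class expression matrix with informative genes mean-shifted.

    Emulates the rapid- vs slow-progressor design directly: ``n_informative``
    genes differ between classes by ``effect_size`` within-class SDs; all
    other genes are pure noise. Returns (expression genes x samples DataFrame,
    labels Series with values 1/2, informative gene id list).
    """
    if n_informative > n_genes:
        raise ConfigurationError("n_informative must not exceed n_genes")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    labels = np.array([1] * n_per_class + [2] * n_per_class)

    means = rng.uniform(5.0, 10.0, size=n_genes)
    sds = rng.uniform(0.3, 1.5, size=n_genes)
    expr = means[:, None] + sds[:, None] * rng.standard_normal((n_genes, n))
    info_idx = np.sort(rng.choice(n_genes, size=n_informative, replace=False))
    # shift class 2 up by effect_size within-class SDs on informative genes
    expr[np.ix_(info_idx, np.flatnonzero(labels == 2))] += (
        effect_size * sds[info_idx][:, None])

    expr_df = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    label_s = pd.Series(labels, index=sample_ids, name="progression_class")
    return expr_df, label_s, [gene_ids[i] for i in info_idx]


def write_fixture(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write (expression, clinical, gene_sets, truth) as TSV/GMT/JSON files."""
    expr, clinical, gene_sets, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    io.write_expression(expr, paths["expression"])
    io.write_clinical(clinical, paths["clinical"])
    io.write_gmt(gene_sets, paths["gene_sets"])
    io.write_json({
        "signature_gene_ids": truth.signature_gene_ids,
        "beta_true": truth.beta_true,
        "batch_assignments": truth.batch_assignments,
    }, paths["truth"])
    return paths
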