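"""Synthetic two-group cohort generator with recorded ground truth.

Emulates the structure of a recurrence-prognosis study on count data: miRNA
and mRNA counts with negative-binomial marginals (lognormal baseline means,
gamma-distributed dispersions, lognormal library sizes), planted fold changes
on a configured fraction of features, group-specific miRNA-mRNA dependence
planted through a Gaussian copula on the latent scale, outcome-associated
ordinal clinical covariates, interaction catalogs with decoys, gene-set
collections, and qPCR CT tables linear in log2 expression with technical
replicate noise. Everything is deterministic under the configured seed and the
planted truth is serializable.

For a latent Gaussian correlation rho, the implied population Spearman
correlation of the (continuous) copula is (6/pi) * asin(rho/2); NB
discretization perturbs this only slightly at moderate abundance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "latent_to_spearman",
    "generate_cohort",
    "generate_correlated_counts",
    "generate_interaction_catalog",
    "generate_gene_sets",
    "generate_ct_table",
    "generate_predictor_table",
]

PT_LEVELS = ["pT3a", "pT3b", "pT4"]
# population frequencies of pathological stage in locally advanced disease
PT_CUTS = stats.norm.ppf([0.52, 0.97])
ISUP_CUTS = stats.norm.ppf([0.12, 0.38, 0.62, 0.80])
ISUP_TO_GLEASON = {1: 6, 2: 7, 3: 7, 4: 8, 5: 9}


def latent_to_spearman(rho: float) -> float:
    """Population Spearman coefficient implied by a latent Gaussian correlation."""
    return (6.0 / math.pi) * math.asin(rho / 2.0)


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    ``planted_pairs`` lists (miRNA id, mRNA id, latent rho in the BCR group,
    latent rho in the BRF group); features named there are excluded from the
    DE plant so that each truth record has one cause. ``clinical_effects``
    gives per-covariate latent shifts (log-odds scale) between BCR and BRF.
    """

    n_samples_per_group: int = 30
    n_mirna: int = 60
    n_mrna: int = 300
    frac_de: float = 0.05
    de_fc: float = 4.0
    nb_mean_log_mu: float = 4.0
    nb_mean_log_sigma: float = 1.2
    nb_dispersion: tuple[float, float] = (2.0, 0.05)  # gamma shape, scale
    libsize_cv: float = 0.3
    planted_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    n_decoy_edges: int = 0
    n_ppi_edges: int = 0
    n_tf_edges: int = 0
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: {"isup": 0.8, "pt": 0.6, "gleason": 0.8, "psa": 0.5}
    )
    ct_intercept: float = 30.0
    ct_slope: float = 1.0
    ct_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 4:
            raise ValueError(
                "n_samples_per_group must be >= 4: the Fisher r-to-z variance "
                "1/(n-3) requires n - 3 > 0"
            )
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.de_fc <= 0:
            raise ValueError("de_fc must be positive")
        for src, tgt, r_bcr, r_brf in self.planted_pairs:
            for r in (r_bcr, r_brf):
                if not -1.0 < r < 1.0:
                    raise ValueError(f"latent correlation {r} for ({src}, {tgt}) "
                                     "must lie strictly in (-1, 1)")

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:03d}" for i in range(self.n_mirna)]

    def mrna_ids(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_mrna)]


@dataclass
class SyntheticTruth:
    """Planted ground truth, serializable and round-trippable through JSON."""

    de_features: list[dict]
    diffcor_pairs: list[dict]
    informative_predictors: list[str]
    labels: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)

    def de_feature_ids(self) -> set[str]:
        return {d["feature"] for d in self.de_features}


def _nb_ppf(u: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Quantile function of NB(mean mu, dispersion alpha); Poisson at alpha=0."""
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    if alpha <= 0:
        return stats.poisson.ppf(u, mu).astype(np.int64)
    r = 1.0 / alpha
    p = r / (r + mu)
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw: NB with Var = mu + alpha * mu^2."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    lam = np.where(alpha > 0,
                   rng.gamma(np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), 1.0),
                             np.maximum(alpha, 1e-12) * mu),
                   mu)
    return rng.poisson(lam).astype(np.int64)


def generate_correlated_counts(
    mu_x: float | np.ndarray,
    mu_y: float | np.ndarray,
    dispersion: float | tuple[float, float],
    rho: float,
    n: int,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired NB count vectors with latent Gaussian-copula correlation ``rho``.

    A bivariate standard normal with correlation rho is mapped through the two
    NB quantile functions, so the marginals are exactly NB(mu, dispersion) and
    the (continuous-scale) Spearman correlation is (6/pi)*asin(rho/2).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("latent correlation must lie strictly in (-1, 1)")
    if n < 4:
        raise ValueError("n must be >= 4 (Fisher z requires n - 3 > 0)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    a_x, a_y = dispersion if isinstance(dispersion, tuple) else (dispersion, dispersion)
    z1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho**2) * e
    x = _nb_ppf(stats.norm.cdf(z1), np.broadcast_to(mu_x, (n,)).astype(float), a_x)
    y = _nb_ppf(stats.norm.cdf(z2), np.broadcast_to(mu_y, (n,)).astype(float), a_y)
    return x, y


def _ordinal(rng: np.random.Generator, y: np.ndarray, effect: float,
             cuts: np.ndarray) -> np.ndarray:
    latent = rng.standard_normal(y.size) + effect * y
    return np.searchsorted(cuts, latent) + 1


def generate_cohort(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, SyntheticTruth]:
    """One synthetic cohort: miRNA counts, mRNA counts, metadata, truth.

    Samples are balanced (n per group); planted DE features carry a group
    mean ratio of ``de_fc`` (up in BCR for the "up" direction); planted pairs
    are drawn jointly per group through the Gaussian copula. Identical config
    (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples_per_group
    sample_ids = [f"S{i + 1:03d}" for i in range(2 * n)]
    y = np.array([1] * n + [0] * n)
    groups = np.where(y == 1, "BCR", "BRF")

    mirna_ids = config.mirna_ids()
    mrna_ids = config.mrna_ids()
    id_sets = {"mirna": mirna_ids, "mrna": mrna_ids}
    paired_features = {f for p in config.planted_pairs for f in p[:2]}
    unknown = paired_features - set(mirna_ids) - set(mrna_ids)
    if unknown:
        raise ValueError(f"planted pairs reference unknown features: {sorted(unknown)}")
    seen: set[str] = set()
    for src, tgt, *_ in config.planted_pairs:
        if src in seen or tgt in seen:
            raise ValueError("each feature may appear in at most one planted pair")
        seen.update((src, tgt))

    de_features: list[dict] = []
    matrices: dict[str, CountMatrix] = {}
    feature_params: dict[str, tuple[np.ndarray, float]] = {}  # id -> (mu per sample, alpha)

    for kind, ids in id_sets.items():
        n_feat = len(ids)
        base_mu = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sigma, n_feat)
        shape, scale = config.nb_dispersion
        alpha = rng.gamma(shape, scale, n_feat) if scale > 0 else np.zeros(n_feat)
        sigma = math.sqrt(math.log(1.0 + config.libsize_cv**2))
        lib = rng.lognormal(-0.5 * sigma**2, sigma, 2 * n)
        # plant fold changes on eligible (non-paired) features
        eligible = [i for i, f in enumerate(ids) if f not in paired_features]
        n_de = int(round(config.frac_de * n_feat))
        n_de = min(n_de, len(eligible))
        de_idx = rng.choice(eligible, size=n_de, replace=False) if n_de else np.array([], int)
        mu = np.outer(base_mu, lib)  # features x samples
        for j, i in enumerate(sorted(de_idx)):
            direction = "↑" if j % 2 == 0 else "↓"
            fc = config.de_fc if direction == "↑" else 1.0 / config.de_fc
            mu[i, y == 1] *= fc
            de_features.append({"feature": ids[i], "direction": direction,
                                "fc": config.de_fc})
        counts = _nb_draw(rng, mu, alpha[:, None])
        matrices[kind] = CountMatrix(counts, ids, sample_ids)
        for i, f in enumerate(ids):
            feature_params[f] = (mu[i], float(alpha[i]))

    # overwrite planted-pair rows with copula-coupled draws, group by group
    diffcor_truth: list[dict] = []
    mi = matrices["mirna"].values
    mr = matrices["mrna"].values
    for src, tgt, rho_bcr, rho_brf in config.planted_pairs:
        mu_src, a_src = feature_params[src]
        mu_tgt, a_tgt = feature_params[tgt]
        i_src = mirna_ids.index(src)
        i_tgt = mrna_ids.index(tgt)
        for rho, mask in ((rho_bcr, y == 1), (rho_brf, y == 0)):
            z1 = rng.standard_normal(mask.sum())
            z2 = rho * z1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(mask.sum())
            mi[i_src, mask] = _nb_ppf(stats.norm.cdf(z1), mu_src[mask], a_src)
            mr[i_tgt, mask] = _nb_ppf(stats.norm.cdf(z2), mu_tgt[mask], a_tgt)
        diffcor_truth.append(
            {
                "mirna": src,
                "mrna": tgt,
                "rho_bcr": rho_bcr,
                "rho_brf": rho_brf,
                "target_rs_bcr": latent_to_spearman(rho_bcr),
                "target_rs_brf": latent_to_spearman(rho_brf),
            }
        )

    eff = config.clinical_effects
    meta = pd.DataFrame(
        {
            "group": groups,
            "isup": _ordinal(rng, y, eff.get("isup", 0.0), ISUP_CUTS),
            "pt": [PT_LEVELS[k - 1] for k in
                   _ordinal(rng, y, eff.get("pt", 0.0), PT_CUTS)],
            "psa": np.round(np.exp(math.log(10.0) + eff.get("psa", 0.0) * y
                                   + 0.6 * rng.standard_normal(2 * n)), 2),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    meta["gleason"] = meta["isup"].map(ISUP_TO_GLEASON)

    truth = SyntheticTruth(
        de_features=de_features,
        diffcor_pairs=diffcor_truth,
        informative_predictors=[],
        labels=dict(zip(sample_ids, groups)),
    )
    return matrices["mirna"], matrices["mrna"], meta, truth


def generate_interaction_catalog(
    truth: SyntheticTruth,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Typed edge catalog: planted miRNA-target pairs plus decoy interactions.

    Decoy miRNA-target edges are sampled uniformly without replacement from
    the non-planted (miRNA, mRNA) combinations; optional PPI and TF-target
    decoys connect random gene pairs. No (source, target, type) duplicates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    mirnas = config.mirna_ids()
    genes = config.mrna_ids()
    planted = {(p["mirna"], p["mrna"]) for p in truth.diffcor_pairs}
    rows = [
        {"source": m, "target": g, "edge_type": "miRNA-target",
         "evidence": "validated", "source_db": "planted"}
        for m, g in sorted(planted)
    ]
    candidates = [(m, g) for m in mirnas for g in genes if (m, g) not in planted]
    if config.n_decoy_edges > len(candidates):
        raise ValueError(
            f"requested {config.n_decoy_edges} decoys but only "
            f"{len(candidates)} non-planted pairs exist"
        )
    if config.n_decoy_edges:
        pick = rng.choice(len(candidates), size=config.n_decoy_edges, replace=False)
        for k in sorted(pick):
            m, g = candidates[k]
            rows.append({"source": m, "target": g, "edge_type": "miRNA-target",
                         "evidence": "predicted", "source_db": "decoy"})
    for n_extra, etype in ((config.n_ppi_edges, "PPI"),
                           (config.n_tf_edges, "TF-target")):
        made: set[tuple[str, str]] = set()
        while len(made) < n_extra:
            a, b = rng.choice(len(genes), size=2, replace=False)
            pair = (genes[a], genes[b])
            if pair not in made:
                made.add(pair)
        for a, b in sorted(made):
            rows.append({"source": a, "target": b, "edge_type": etype,
                         "evidence": "n/a", "source_db": "decoy"})
    catalog = pd.DataFrame(rows)
    if catalog.duplicated(["source", "target", "edge_type"]).any():
        raise AssertionError("duplicate (source, target, type) triples")
    return catalog


def generate_gene_sets(
    config: SimConfig,
    n_sets: int = 20,
    set_size: tuple[int, int] = (10, 40),
    mirnas_per_set: int = 2,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, dict], dict[str, list[str]]]:
    """Random gene-set collection plus a miRNA-to-set annotation table."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    genes = config.mrna_ids()
    mirnas = config.mirna_ids()
    sets: dict[str, dict] = {}
    annotation: dict[str, list[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        members = [genes[i] for i in sorted(rng.choice(len(genes), size, replace=False))]
        set_id = f"SET{s + 1:03d}"
        sets[set_id] = {"name": f"synthetic pathway {s + 1}", "members": members}
        if mirnas_per_set:
            picks = rng.choice(len(mirnas), mirnas_per_set, replace=False)
            annotation[set_id] = [mirnas[i] for i in sorted(picks)]
    return sets, annotation


def generate_ct_table(
    expression: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """qPCR CT table: CT = intercept - slope * log2(expression) + noise.

    ``expression`` is samples x assays (strictly positive, on the relative
    scale where the reference assay is 1); each (sample, assay) gets
    ``n_replicates`` technical replicate rows.
    """
    if (expression.to_numpy() <= 0).any():
        raise ValueError("expression values must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rows = []
    for sample in expression.index:
        for assay in expression.columns:
            base = config.ct_intercept - config.ct_slope * math.log2(
                float(expression.loc[sample, assay])
            )
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "assay": assay,
                        "replicate": rep,
                        "ct": base + config.ct_noise_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


def generate_predictor_table(
    n_per_class: int = 100,
    expression_effect: float = 1.5,
    ordinal_effect: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Six-predictor benchmark table for the recurrence classifier.

    Three gene-expression predictors and one miRNA predictor are unit-variance
    Gaussians separated by ``expression_effect`` between classes; ISUP and pT
    are informative ordinals from a shifted latent Gaussian. Labels: BCR = 1.
    """
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    cols = {}
    for name in ["gene_ALDH3A2_like", "gene_ODF2_like", "gene_QSOX2_like",
                 "mirna_503_like"]:
        cols[name] = rng.standard_normal(y.size) + expression_effect * y
    cols["isup"] = _ordinal(rng, y, ordinal_effect, ISUP_CUTS).astype(float)
    cols["pt"] = _ordinal(rng, y, ordinal_effect, PT_CUTS).astype(float)
    x = pd.DataFrame(cols, index=[f"P{i + 1:03d}" for i in range(y.size)])
    perm = rng.permutation(y.size)
    return x.iloc[perm], y[perm]
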