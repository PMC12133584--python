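"""Synthetic connectome/behavior generator with planted brain–behavior signal.

Emulates the statistical structure the CPM pipeline assumes, at the study's
scale (92 subjects, a Gordon-like 333-parcel atlas with 12 named networks):

* a standard-normal latent cognitive trait per subject;
* designated *planted* positive/negative edge sets, concentrated in chosen
  network pairs, whose connectivity is coupled to the trait with slope
  ``effect_beta`` (sign-flipped for a *discordant* subject subgroup);
* an NIH-Toolbox-like outcome (mean 100, SD 15) loading on the trait;
* covariates stereotypically coupled to the trait (parental SES positively,
  antipsychotic exposure negatively), by default only in concordant subjects,
  so that covariate–outcome associations break exactly in the subgroup the
  model mispredicts.

Generation is at the FC-matrix level; no time series, spatial autocorrelation
or site structure is simulated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CANONICAL_NETWORKS,
    UNASSIGNED,
    BehavioralTable,
    ConnectomeSet,
    NetworkAtlas,
    edge_pairs,
    n_edges,
    write_atlas,
    write_behavior,
    write_connectomes,
)

logger = logging.getLogger(__name__)

#: Published community sizes of the Gordon 333-parcel atlas (47 unassigned).
GORDON_NETWORK_SIZES: dict[str, int] = {
    "AUD": 24, "CO": 40, "CP": 5, "DAN": 32, "DMN": 41, "FPN": 24,
    "RSP": 8, "SAL": 4, "SM": 38, "SML": 8, "VAN": 23, "VIS": 39,
}


def gordon_like_atlas() -> NetworkAtlas:
    """A 333-parcel atlas with the Gordon network sizes, in label blocks."""
    labels: list[str] = []
    for net in CANONICAL_NETWORKS:
        labels += [net] * GORDON_NETWORK_SIZES[net]
    labels += [UNASSIGNED] * (333 - len(labels))
    return NetworkAtlas(np.asarray(labels, dtype=object))


def balanced_atlas(
    parcels_per_network: int = 4,
    networks: tuple[str, ...] = CANONICAL_NETWORKS,
    n_unassigned: int = 0,
) -> NetworkAtlas:
    """A small atlas with equal-size networks, for desk-scale runs."""
    labels = [net for net in networks for _ in range(parcels_per_network)]
    labels += [UNASSIGNED] * n_unassigned
    return NetworkAtlas(np.asarray(labels, dtype=object))


def _edge_lookup(n_parcels: int) -> np.ndarray:
    iu, ju = edge_pairs(n_parcels)
    lut = np.full((n_parcels, n_parcels), -1, dtype=int)
    lut[iu, ju] = np.arange(iu.size)
    lut[ju, iu] = np.arange(iu.size)
    return lut


def edges_between(atlas: NetworkAtlas, net_a: str, net_b: str) -> np.ndarray:
    """All edge indices with one endpoint in net_a and the other in net_b."""
    iu, ju = edge_pairs(atlas.n_parcels)
    la, lb = atlas.labels[iu], atlas.labels[ju]
    mask = ((la == net_a) & (lb == net_b)) | ((la == net_b) & (lb == net_a))
    return np.flatnonzero(mask)


@dataclass
class SyntheticConfig:
    """Study-condition parameters for one synthetic dataset.

    Defaults are the emulated study's conditions: 92 subjects on a 333-parcel
    Gordon-like atlas, ~1% of edges planted (half positive, concentrated in
    DMN–VIS; half negative, in SM–RSP), trait coupling ``effect_beta=0.5``
    against unit edge noise, an outcome on the NIH-Toolbox scale
    (mean 100, SD 15), and SES/antipsychotic-exposure couplings ±0.5 applied
    to concordant subjects only.
    """

    n_subjects: int = 92
    atlas: NetworkAtlas | None = None
    planted_positive: np.ndarray | None = None  # explicit edge indices
    planted_negative: np.ndarray | None = None
    planted_pairs_positive: dict[tuple[str, str], int] | None = None
    planted_pairs_negative: dict[tuple[str, str], int] | None = None
    planted_fraction: float = 0.01
    default_pair_positive: tuple[str, str] = ("DMN", "VIS")
    default_pair_negative: tuple[str, str] = ("SM", "RSP")
    effect_beta: float = 0.5
    edge_noise_sd: float = 1.0
    baseline_sd: float = 0.3
    outcome_loading: float = 1.0
    outcome_noise_sd: float = 0.5
    outcome_mean: float = 100.0
    outcome_sd: float = 15.0
    covariate_couplings: dict[str, float] = field(
        default_factory=lambda: {"SES": 0.5, "antipsychotic_exposure": -0.5}
    )
    stereotype_concordant_only: bool = True
    discordant_fraction: float = 0.0
    squash_edges: bool = False  # tanh-squash edges into (-1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atlas is None:
            self.atlas = gordon_like_atlas()
        if not 0.0 <= self.discordant_fraction < 1.0:
            raise ValueError("discordant_fraction must be in [0, 1)")
        if self.outcome_loading == 0 and self.outcome_noise_sd == 0:
            raise ValueError("outcome would be constant (zero loading and noise)")
        for name, rho in self.covariate_couplings.items():
            if abs(rho) >= 1:
                raise ValueError(f"covariate coupling {name}={rho} must be in (-1, 1)")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    trait: np.ndarray
    concordant: np.ndarray  # bool per subject
    planted_positive: np.ndarray
    planted_negative: np.ndarray


def planted_edge_outcome_correlation(config: SyntheticConfig) -> float:
    """Population Pearson correlation between a planted positive edge and the
    outcome, in concordant subjects:

        r = beta * loading / (sqrt(beta^2 + sigma_e^2) * sqrt(loading^2 + sigma_y^2))

    (negated for planted negative edges). Used as a closed-form oracle for the
    generator's large-n behavior.
    """
    num = config.effect_beta * config.outcome_loading
    den = np.sqrt(config.effect_beta**2 + config.edge_noise_sd**2) * np.sqrt(
        config.outcome_loading**2 + config.outcome_noise_sd**2
    )
    return float(num / den)


def _resolve_planted(config: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    atlas = config.atlas
    E = n_edges(atlas.n_parcels)

    def sample_pairs(pairs: dict[tuple[str, str], int], taken: np.ndarray) -> np.ndarray:
        chosen: list[np.ndarray] = []
        for (a, b), count in pairs.items():
            pool = np.setdiff1d(edges_between(atlas, a, b), taken)
            if count > pool.size:
                raise ValueError(
                    f"cannot plant {count} edges between {a} and {b}; only "
                    f"{pool.size} available"
                )
            pick = rng.choice(pool, size=count, replace=False)
            chosen.append(pick)
            taken = np.concatenate([taken, pick])
        return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)

    if config.planted_positive is not None or config.planted_negative is not None:
        pos = np.asarray(
            config.planted_positive if config.planted_positive is not None else [], dtype=int
        )
        neg = np.asarray(
            config.planted_negative if config.planted_negative is not None else [], dtype=int
        )
    else:
        per_side = max(1, int(round(config.planted_fraction * E / 2)))
        pairs_pos = config.planted_pairs_positive or {config.default_pair_positive: per_side}
        pairs_neg = config.planted_pairs_negative or {config.default_pair_negative: per_side}
        pos = sample_pairs(pairs_pos, np.array([], dtype=int))
        neg = sample_pairs(pairs_neg, pos)
    if np.intersect1d(pos, neg).size:
        raise ValueError("planted positive and negative edge sets overlap")
    if pos.size and pos.max() >= E or neg.size and neg.max() >= E:
        raise ValueError("planted edge index out of range")
    return pos, neg


def generate(config: SyntheticConfig) -> tuple[ConnectomeSet, BehavioralTable, GroundTruth]:
    """Draw one dataset under ``config``; bit-reproducible from its seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    atlas = config.atlas
    n, E = config.n_subjects, n_edges(atlas.n_parcels)
    pos, neg = _resolve_planted(config, rng)

    trait = rng.standard_normal(n)
    concordant = np.ones(n, dtype=bool)
    n_disc = int(round(config.discordant_fraction * n))
    if n_disc:
        concordant[rng.choice(n, size=n_disc, replace=False)] = False
    sign = np.where(concordant, 1.0, -1.0)

    baseline = rng.normal(0.0, config.baseline_sd, size=E)
    edges = baseline[None, :] + rng.normal(0.0, config.edge_noise_sd, size=(n, E))
    coupling = config.effect_beta * trait * sign
    edges[:, pos] += coupling[:, None]
    edges[:, neg] -= coupling[:, None]
    if config.squash_edges:
        edges = np.tanh(edges)

    latent = config.outcome_loading * trait + rng.normal(
        0.0, config.outcome_noise_sd, size=n
    )
    latent_sd = np.sqrt(config.outcome_loading**2 + config.outcome_noise_sd**2)
    y = config.outcome_mean + config.outcome_sd * latent / latent_sd

    subject_ids = [f"sub-{k + 1:04d}" for k in range(n)]
    behav = pd.DataFrame(index=pd.Index(subject_ids, name="subject_id"))
    behav["total"] = y

    apply_to = concordant if config.stereotype_concordant_only else np.ones(n, dtype=bool)

    def coupled(name: str, loc: float, scale: float, clip_low: float | None = None) -> np.ndarray:
        rho = config.covariate_couplings.get(name, 0.0)
        z = rho * trait * apply_to + rng.normal(0.0, np.sqrt(1 - rho**2), size=n)
        v = loc + scale * z
        return np.clip(v, clip_low, None) if clip_low is not None else v

    behav["age"] = np.round(rng.normal(23.0, 3.5, size=n), 1)
    behav["sex"] = rng.choice(["F", "M"], size=n)
    behav["race"] = rng.choice(["asian", "black", "other", "white"], size=n)
    behav["SES"] = np.round(coupled("SES", 50.0, 10.0), 2)
    behav["antipsychotic_exposure"] = np.round(
        coupled("antipsychotic_exposure", 24.0, 12.0, clip_low=0.0), 1
    )
    behav["PANSS_pos"] = np.round(np.clip(rng.normal(15.0, 4.0, size=n), 7, None), 1)
    behav["PANSS_neg"] = np.round(np.clip(rng.normal(14.0, 5.0, size=n), 7, None), 1)
    behav["head_motion"] = np.round(np.abs(rng.normal(0.12, 0.04, size=n)), 4)

    conn = ConnectomeSet(subject_ids, edges, atlas.n_parcels)
    table = BehavioralTable(
        behav,
        outcomes=("total",),
        covariates=(
            "age", "sex", "race", "SES", "antipsychotic_exposure",
            "PANSS_pos", "PANSS_neg", "head_motion",
        ),
    )
    truth = GroundTruth(trait, concordant, pos, neg)
    logger.info(
        "generated N=%d P=%d E=%d (planted +%d/-%d, discordant %d)",
        n, atlas.n_parcels, E, pos.size, neg.size, n_disc,
    )
    return conn, table, truth


def write_fixture(
    conn: ConnectomeSet,
    atlas: NetworkAtlas,
    behavior: BehavioralTable,
    truth: GroundTruth | None,
    directory: str | Path,
    fmt: str = "matrices",
) -> Path:
    """Write a dataset in the package's text input formats (plus a
    ground-truth sidecar when available); round-trips through read_inputs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "matrices":
        write_connectomes(conn, directory / "connectomes", fmt="matrices")
    else:
        write_connectomes(conn, directory / "edges.tsv", fmt="edge_table")
    write_atlas(atlas, directory / "atlas.tsv")
    write_behavior(behavior, directory / "behavior.tsv")
    if truth is not None:
        iu, ju = edge_pairs(atlas.n_parcels)
        sidecar = {
            "planted_positive_pairs": [
                [int(iu[e]), int(ju[e])] for e in truth.planted_positive
            ],
            "planted_negative_pairs": [
                [int(iu[e]), int(ju[e])] for e in truth.planted_negative
            ],
            "concordant": truth.concordant.astype(int).tolist(),
            "trait": truth.trait.tolist(),
        }
        (directory / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return directory


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Named study conditions.

    * ``tiny`` — 24 subjects, 20 parcels over 4 networks; smoke tests.
    * ``study-scale`` — the default 92 × 333 configuration.
    * ``null`` — no brain–behavior coupling (effect_beta = 0), 46 parcels.
    * ``discordant`` — the misprediction scenario: 92 subjects on a 72-parcel
      atlas, a widespread planted set (DMN–VIS and DAN–VAN positive, SM–RSP
      and VIS–AUD negative, 120 edges), 30% discordant subjects, and the
      stereotypical SES / antipsychotic-exposure couplings confined to
      concordant subjects. The planted density was calibrated once, by
      simulation, so the share of frequently misclassified subjects (MI > 0.5)
      lands near the one-third observed in early-psychosis cohorts.
    """
    if name == "tiny":
        return SyntheticConfig(
            n_subjects=24,
            atlas=balanced_atlas(5, ("DMN", "VIS", "SM", "FPN")),
            planted_fraction=0.08,
            default_pair_positive=("DMN", "VIS"),
            default_pair_negative=("SM", "FPN"),
            seed=seed,
        )
    if name == "study-scale":
        return SyntheticConfig(seed=seed)
    if name == "null":
        return SyntheticConfig(
            n_subjects=92,
            atlas=balanced_atlas(3, CANONICAL_NETWORKS, n_unassigned=10),  # 46 parcels
            effect_beta=0.0,
            seed=seed,
        )
    if name == "discordant":
        return SyntheticConfig(
            n_subjects=92,
            atlas=balanced_atlas(6),
            planted_pairs_positive={("DMN", "VIS"): 30, ("DAN", "VAN"): 30},
            planted_pairs_negative={("SM", "RSP"): 30, ("VIS", "AUD"): 30},
            discordant_fraction=0.3,
            seed=seed,
        )
    raise ValueError(
        f"unknown preset {name!r} (try tiny, study-scale, null, discordant)"
    )
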