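"""Synthetic multi-pen agonistic-behaviour studies with known ground truth.

The generator emulates a fattening-unit observational study: ~29 pens of
10-15 pigs observed over six sessions, a few hundred agonistic events
concentrated in few dyads, a latent dominance hierarchy, a fraction of
animals that never engage (isolated), and feeder/weight records whose
derived traits carry configurable rank correlations with out-degree.

Model
-----
* Each animal gets a latent dominance score d_i ~ N(0, 1) and is isolated
  with probability ``isolation_prob`` (isolated animals neither initiate
  nor receive attacks).
* For every ordered pair (i, j) of non-isolated pen-mates the number of
  attacks i -> j over the whole study is Poisson with mean
  lambda * exp(alpha * (d_i - d_j)), optionally multiplied by
  ``block_factor`` when i and j share a planted community block. The
  exponential rate makes attacks flow down the hierarchy and concentrates
  counts in few dyads, as sparse pen aggression does.
* ``base_attack_rate`` (lambda) is, by default, calibrated so the expected
  total event count across the study equals ``target_total_events``,
  using E[exp(alpha (d_i - d_j))] = exp(alpha^2).
* Each event draws an ethogram behaviour from ``behaviour_type_probs``
  and a session uniformly.
* Traits couple to the aggression network through a Gaussian copula on
  pooled out-degree mid-ranks: for each configured trait, a latent normal
  score with Pearson correlation 2 sin(pi rho_s / 6) to the rank-normal
  out-degree score is drawn (so the *Spearman* correlation targets
  rho_s), then mapped onto the trait's marginal scale. Feeder visit logs
  and weight series are synthesized around those per-animal targets with
  small day-level noise, so the traits the pipeline derives from the raw
  logs inherit the planted correlations.

Everything is reproducible bit-exactly from (config, seed); per-pen
random substreams are keyed by pen index so pens are independent of
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import degree_centralities
from .ingest import (
    BEHAVIOURS,
    ObservationRecord,
    PenNetwork,
    PenRoster,
    build_pen_network,
)

__all__ = ["SimConfig", "SyntheticStudy", "simulate_pen", "simulate_traits",
           "simulate_study", "write_study", "DEFAULT_PEN_SIZES"]

#: 29 pens totalling 326 animals: 11 pens of 11 and 8 pens of 12 (the two
#: equal-size groups used for network comparison) plus 10 pens of 10 or 13.
DEFAULT_PEN_SIZES: tuple[int, ...] = (11,) * 11 + (12,) * 8 + (10,) * 7 + (13,) * 3

#: Traits that can be coupled to out-degree, with marginal (mean, sd) on
#: realistic fattening-pig scales. FInt is in minutes between visit starts.
TRAIT_MARGINALS: dict[str, tuple[float, float]] = {
    "FR": (40.6, 8.0),     # g/min
    "OT": (59.5, 9.7),     # min/day
    "FF": (10.7, 2.9),     # visits/day
    "FInt": (80.0, 18.0),  # min between consecutive visit starts
    "ADG": (0.81, 0.10),   # kg/day
    "BF": (18.5, 4.2),     # mm at 180 d
}

_TRAIT_FLOORS = {"FR": 10.0, "OT": 15.0, "FF": 2.0, "FInt": 10.0,
                 "ADG": 0.2, "BF": 5.0}

WEIGH_AGES = tuple(range(65, 180, 14))      # biweekly, 9 records/animal
BACKFAT_AGES = (65, 93, 121, 149, 177)      # 5 records/animal
FEEDING_DAYS = tuple(range(65, 180))        # one feeder day per age day


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults reproduce the emulated study conditions: 29 pens of 10-15
    animals (326 total), six observation sessions, behaviour mix
    74/19/5/2% (head-knock/bite/fight/chase), ~21% isolated animals,
    ~551 expected events in total, and small out-degree/trait rank
    correlations of the configured signs.
    """

    pen_sizes: tuple[int, ...] = DEFAULT_PEN_SIZES
    n_sessions: int = 6
    behaviour_type_probs: tuple[float, float, float, float] = (
        0.74, 0.19, 0.05, 0.02,
    )
    dominance_effect: float = 0.5   # alpha; see docs for the calibration
    isolation_prob: float = 0.21
    base_attack_rate: float | None = None  # lambda; None -> calibrate
    target_total_events: float = 551.0
    community_blocks: int | None = None
    block_factor: float = 4.0
    trait_effects: dict[str, float] = field(
        default_factory=lambda: {
            "FR": -0.18, "OT": 0.15, "FF": 0.10, "FInt": -0.11,
            "ADG": -0.01, "BF": -0.01,
        }
    )

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.pen_sizes):
            raise ValueError("every pen needs >= 2 animals")
        probs = np.asarray(self.behaviour_type_probs, dtype=float)
        if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("behaviour_type_probs must be in [0,1] and sum to 1")
        if not 0 <= self.isolation_prob <= 1:
            raise ValueError("isolation_prob must be in [0, 1]")
        if self.base_attack_rate is not None and self.base_attack_rate <= 0:
            raise ValueError("base_attack_rate must be positive")
        for trait, rho in self.trait_effects.items():
            if trait not in TRAIT_MARGINALS:
                raise ValueError(f"unknown trait {trait!r} in trait_effects")
            if not -1 < rho < 1:
                raise ValueError(
                    f"infeasible correlation for ('out_degree', {trait!r}): "
                    f"{rho} is outside (-1, 1)"
                )

    @property
    def attack_rate(self) -> float:
        """lambda: given, or calibrated to the expected total event count."""
        if self.base_attack_rate is not None:
            return self.base_attack_rate
        dyads = sum(n * (n - 1) for n in self.pen_sizes)
        expected_per_unit = (
            dyads
            * (1 - self.isolation_prob) ** 2
            * float(np.exp(self.dominance_effect**2))
        )
        if expected_per_unit == 0:
            return 1.0  # no eligible dyads exist; value is immaterial
        return self.target_total_events / expected_per_unit


@dataclass(frozen=True)
class SyntheticStudy:
    """Observable tables plus the latent truth they were generated from."""

    config: SimConfig
    seed: int
    rosters: list[PenRoster]
    records: list[ObservationRecord]
    feeder: pd.DataFrame
    weights: pd.DataFrame
    backfat: pd.DataFrame
    latent: pd.DataFrame        # animal_id, pen_id, dominance, isolated, block
    trait_targets: pd.DataFrame  # per-animal marginal targets used for logs

    def networks(self) -> list[PenNetwork]:
        by_pen: dict[str, list[ObservationRecord]] = {
            r.pen_id: [] for r in self.rosters
        }
        for rec in self.records:
            by_pen[rec.pen_id].append(rec)
        return [build_pen_network(by_pen[r.pen_id], r) for r in self.rosters]


def _pen_rng(seed: int, pen_index: int) -> np.random.Generator:
    # substream keyed by pen index, independent of iteration order
    return np.random.default_rng([seed, pen_index])


def simulate_pen(
    config: SimConfig, seed: int, pen_index: int
) -> tuple[PenRoster, list[ObservationRecord], pd.DataFrame]:
    """Generate one pen: roster, agonistic events, and its latent truth."""
    rng = _pen_rng(seed, pen_index)
    n = config.pen_sizes[pen_index]
    pen_id = f"p{pen_index + 1:02d}"
    animals = tuple(f"{pen_id}-a{k + 1:02d}" for k in range(n))
    sex_group = "gilts" if pen_index < 20 else "barrows"
    roster = PenRoster(pen_id=pen_id, animals=animals, sex_group=sex_group)

    dominance = rng.standard_normal(n)
    isolated = rng.random(n) < config.isolation_prob
    if config.community_blocks:
        block = rng.permutation(np.arange(n) % config.community_blocks)
    else:
        block = np.zeros(n, dtype=int)

    lam = config.attack_rate
    alpha = config.dominance_effect
    records: list[ObservationRecord] = []
    for i in range(n):
        if isolated[i]:
            continue
        for j in range(n):
            if i == j or isolated[j]:
                continue
            mu = lam * float(np.exp(alpha * (dominance[i] - dominance[j])))
            if config.community_blocks and block[i] == block[j]:
                mu *= config.block_factor
            count = int(rng.poisson(mu))
            if count == 0:
                continue
            beh_idx = rng.choice(len(BEHAVIOURS), size=count,
                                 p=config.behaviour_type_probs)
            sessions = rng.integers(1, config.n_sessions + 1, size=count)
            for b, s in zip(beh_idx, sessions):
                records.append(
                    ObservationRecord(
                        pen_id=pen_id,
                        session_id=f"s{s}",
                        behaviour=BEHAVIOURS[b],
                        initiator=animals[i],
                        receiver=animals[j],
                    )
                )
    latent = pd.DataFrame(
        {
            "animal_id": animals,
            "pen_id": pen_id,
            "dominance": dominance,
            "isolated": isolated,
            "block": block,
        }
    )
    return roster, records, latent


def _copula_targets(
    out_degree: pd.Series, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-animal trait targets rank-coupled to pooled out-degree."""
    ranks = stats.rankdata(out_degree.to_numpy())       # mid-ranks
    z_out = stats.norm.ppf(ranks / (len(ranks) + 1.0))
    sd = z_out.std()
    z_out = z_out / sd if sd > 0 else np.zeros_like(z_out)
    targets = {}
    for trait, (mean, scale) in TRAIT_MARGINALS.items():
        rho_s = config.trait_effects.get(trait, 0.0)
        rho_g = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Spearman -> Pearson
        z = rho_g * z_out + np.sqrt(1.0 - rho_g**2) * rng.standard_normal(
            len(z_out)
        )
        targets[trait] = np.maximum(mean + scale * z, _TRAIT_FLOORS[trait])
    frame = pd.DataFrame(targets, index=out_degree.index)
    frame.index.name = "animal_id"
    return frame


def simulate_traits(
    networks: list[PenNetwork], config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthesize feeder logs and measurement series around planted targets.

    Returns (feeder, weights, backfat, trait_targets). Coupling uses the
    out-degrees of the supplied networks pooled over pens.
    """
    rng = np.random.default_rng([seed, 1_000_000])
    out_deg: dict[str, int] = {}
    for net in networks:
        _, out, _ = degree_centralities(net)
        out_deg.update(out)
    out_series = pd.Series(out_deg).sort_index()
    targets = _copula_targets(out_series, config, rng)

    feeder_parts = []
    weight_rows = []
    backfat_rows = []
    ages = np.asarray(WEIGH_AGES, dtype=float)
    bf_ages = np.asarray(BACKFAT_AGES, dtype=float)
    for animal in targets.index:
        t = targets.loc[animal]
        # --- feeder visits -------------------------------------------------
        n_visits_day = rng.poisson(t["FF"], size=len(FEEDING_DAYS))
        day_col, start_col, dur_col, intake_col = [], [], [], []
        for day, v in zip(FEEDING_DAYS, n_visits_day):
            if v == 0:
                continue
            t0 = rng.uniform(360.0, 480.0)
            gaps = t["FInt"] * rng.gamma(16.0, 1.0 / 16.0, size=v - 1)
            starts = t0 + np.concatenate(([0.0], np.cumsum(gaps)))
            durations = (t["OT"] / v) * rng.gamma(25.0, 1.0 / 25.0, size=v)
            intakes = durations * t["FR"] * rng.gamma(100.0, 1.0 / 100.0,
                                                      size=v)
            day_col.extend([day] * v)
            start_col.extend(starts)
            dur_col.extend(durations)
            intake_col.extend(intakes)
        feeder_parts.append(
            pd.DataFrame(
                {
                    "animal": animal,
                    "day": day_col,
                    "start_min": np.round(start_col, 2),
                    "duration_min": np.round(dur_col, 3),
                    "intake_g": np.round(intake_col, 1),
                }
            )
        )
        # --- weight series -------------------------------------------------
        intercept = rng.normal(-35.0, 5.0)
        w = intercept + t["ADG"] * ages + rng.normal(0.0, 1.0, size=len(ages))
        weight_rows.append(
            pd.DataFrame(
                {"animal": animal, "age_days": ages.astype(int),
                 "weight_kg": np.round(w, 2)}
            )
        )
        # --- back-fat series -----------------------------------------------
        slope = 0.075 * t["BF"] / 18.5
        bf0 = t["BF"] - 180.0 * slope
        bf = bf0 + slope * bf_ages + rng.normal(0.0, 0.8, size=len(bf_ages))
        backfat_rows.append(
            pd.DataFrame(
                {"animal": animal, "age_days": bf_ages.astype(int),
                 "backfat_mm": np.round(bf, 2)}
            )
        )
    feeder = pd.concat(feeder_parts, ignore_index=True)
    weights = pd.concat(weight_rows, ignore_index=True)
    backfat = pd.concat(backfat_rows, ignore_index=True)
    return feeder, weights, backfat, targets


def simulate_study(config: SimConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full multi-pen study (events, feeder logs, weights)."""
    config = config or SimConfig()
    rosters: list[PenRoster] = []
    records: list[ObservationRecord] = []
    latent_parts: list[pd.DataFrame] = []
    for pen_index in range(len(config.pen_sizes)):
        roster, recs, latent = simulate_pen(config, seed, pen_index)
        rosters.append(roster)
        records.extend(recs)
        latent_parts.append(latent)
    latent = pd.concat(latent_parts, ignore_index=True)

    by_pen: dict[str, list[ObservationRecord]] = {r.pen_id: [] for r in rosters}
    for rec in records:
        by_pen[rec.pen_id].append(rec)
    networks = [build_pen_network(by_pen[r.pen_id], r) for r in rosters]
    feeder, weights, backfat, targets = simulate_traits(networks, config, seed)
    return SyntheticStudy(
        config=config,
        seed=seed,
        rosters=rosters,
        records=records,
        feeder=feeder,
        weights=weights,
        backfat=backfat,
        latent=latent,
        trait_targets=targets,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the observable tables in the CSV schemas the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": out / "observations.csv",
        "roster": out / "roster.csv",
        "feeder": out / "feeder.csv",
        "weights": out / "weights.csv",
        "backfat": out / "backfat.csv",
        "latent_truth": out / "latent_truth.csv",
    }
    obs = pd.DataFrame(
        [
            {
                "pen": r.pen_id,
                "session": r.session_id,
                "behaviour": r.behaviour,
                "initiator": r.initiator,
                "receiver": r.receiver,
            }
            for r in study.records
        ]
    )
    obs.to_csv(paths["observations"], index=False)
    roster = pd.DataFrame(
        [
            {"pen": r.pen_id, "animal": a, "sex_group": r.sex_group}
            for r in study.rosters
            for a in r.animals
        ]
    )
    roster.to_csv(paths["roster"], index=False)
    study.feeder.to_csv(paths["feeder"], index=False)
    study.weights.to_csv(paths["weights"], index=False)
    study.backfat.to_csv(paths["backfat"], index=False)
    study.latent.to_csv(paths["latent_truth"], index=False)
    return paths


def with_effects(config: SimConfig, **effects: float) -> SimConfig:
    """Convenience: a copy of ``config`` with some trait effects replaced."""
    merged = dict(config.trait_effects)
    merged.update(effects)
    return replace(config, trait_effects=merged)
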