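"""Seeded generators for docking-score, activity-record and kinetics data.

The generators reproduce the statistical structure the screening method
assumes, so the whole pipeline is testable without any external data:

* inhibitors have more negative (more favorable) allosteric scores than
  non-inhibitors;
* the orthosteric scores of inhibitors are bimodal with a low-density gap
  between the modes, while non-inhibitors form one broad component; a
  per-class fraction of compounds is "bumped" (no valid orthosteric pose,
  score +inf); nothing is bumped from the promiscuous allosteric site;
* kinetics plates follow the mixed-inhibition velocity model with
  multiplicative lognormal noise.

Every generator is a pure function of its config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import mixed_inhibition
from .score_data import (
    BUMPED,
    ActivityRecord,
    CompoundRecord,
    Label,
    PotencyBand,
    assign_potency_band,
)


@dataclass(frozen=True)
class ScoreGenConfig:
    """Docking-score generator settings (kcal/mol, µM).

    Defaults emulate a screening reference set in which ~7.8% of compounds
    are inhibitors, inhibitor allosteric scores sit ~10 kcal/mol below
    non-inhibitors', inhibitor orthosteric scores flank a gap at roughly
    (−27, −19), and an appreciable fraction of compounds is bumped from
    the narrow orthosteric site.
    """

    n: int = 1000
    inhibitor_fraction: float = 0.078
    # (location, scale) of the Gaussian allosteric score per class
    allo_inhibitor: tuple[float, float] = (-31.0, 6.0)
    allo_non_inhibitor: tuple[float, float] = (-21.0, 6.0)
    # inhibitors: two components flanking the gap, (loc, scale, weight of low component)
    ortho_inhibitor_low: tuple[float, float] = (-33.0, 4.0)
    ortho_inhibitor_high: tuple[float, float] = (-10.0, 5.0)
    ortho_inhibitor_low_weight: float = 0.5
    # non-inhibitors: one broad component
    ortho_non_inhibitor: tuple[float, float] = (-10.0, 12.0)
    bump_prob_inhibitor: float = 0.05
    bump_prob_non_inhibitor: float = 0.12
    allo_bump_prob: float = 0.0  # the allosteric site bumps nothing
    strong_fraction: float = 17.0 / 78.0  # strong : all inhibitors
    seed: int = 0

    def validate(self) -> None:
        probs = (
            self.inhibitor_fraction,
            self.bump_prob_inhibitor,
            self.bump_prob_non_inhibitor,
            self.allo_bump_prob,
            self.strong_fraction,
            self.ortho_inhibitor_low_weight,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not self.ortho_inhibitor_low[0] < self.ortho_inhibitor_high[0]:
            raise ValueError("inhibitor orthosteric components must straddle the gap")


@dataclass(frozen=True)
class KineticsGenConfig:
    """Kinetics plate generator settings.

    Default design: six substrate concentrations (two-fold dilutions,
    1.56–50 µM) crossed with a nine-point inhibitor titration (three-fold
    dilutions up to 200 µM plus the 0 µM control), four technical and two
    experimental replicates, 5% multiplicative noise. Generative truths
    default to a potent mixed-type inhibitor (K_i 1.4 µM, α 4.7).
    """

    v_max: float = 100.0
    k_m: float = 10.0
    k_i: float = 1.4
    alpha: float = 4.7
    substrate_concs: tuple[float, ...] = (1.56, 3.125, 6.25, 12.5, 25.0, 50.0)
    inhibitor_concs: tuple[float, ...] = (
        0.0, 0.091, 0.274, 0.823, 2.47, 7.41, 22.2, 66.7, 200.0,
    )
    noise_cv: float = 0.05
    n_tech: int = 4
    n_exp: int = 2
    scale: float = 1000.0  # fluorescence counts per velocity unit
    seed: int = 0

    def validate(self) -> None:
        if min(self.v_max, self.k_m, self.k_i, self.alpha) <= 0:
            raise ValueError("kinetic truths must be positive")
        if not self.substrate_concs or not self.inhibitor_concs:
            raise ValueError("concentration lists must be nonempty")
        if self.noise_cv < 0 or self.n_tech < 1 or self.n_exp < 1:
            raise ValueError("invalid noise/replicate settings")


def generate_scores(config: ScoreGenConfig) -> list[CompoundRecord]:
    """Draw a labeled docking-score table.

    Labels are exact ground truth (not noisy); AC50 values are drawn
    log-uniformly within the strong (<1 µM) or weak ([1, 100) µM) band so
    both potency bands are populated. Deterministic given the config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    is_inh = rng.random(n) < config.inhibitor_fraction

    allo = np.where(
        is_inh,
        rng.normal(*config.allo_inhibitor, size=n),
        rng.normal(*config.allo_non_inhibitor, size=n),
    )
    allo_bumped = rng.random(n) < config.allo_bump_prob

    low = rng.random(n) < config.ortho_inhibitor_low_weight
    ortho_inh = np.where(
        low,
        rng.normal(*config.ortho_inhibitor_low, size=n),
        rng.normal(*config.ortho_inhibitor_high, size=n),
    )
    ortho = np.where(is_inh, ortho_inh, rng.normal(*config.ortho_non_inhibitor, size=n))
    bump_p = np.where(is_inh, config.bump_prob_inhibitor, config.bump_prob_non_inhibitor)
    ortho_bumped = rng.random(n) < bump_p

    strong = rng.random(n) < config.strong_fraction
    ac50 = np.where(
        strong,
        10.0 ** rng.uniform(-2.0, 0.0, size=n),  # 0.01–1 µM
        10.0 ** rng.uniform(0.0, 2.0, size=n),  # 1–100 µM
    )

    records = []
    width = len(str(max(n, 1)))
    for k in range(n):
        label = Label.INHIBITOR if is_inh[k] else Label.NON_INHIBITOR
        band = PotencyBand.NONE
        a50 = None
        if is_inh[k]:
            a50 = float(ac50[k])
            band = PotencyBand(assign_potency_band(a50))
        records.append(
            CompoundRecord(
                compound_id=f"SYN{k:0{width}d}",
                ortho_score=BUMPED if ortho_bumped[k] else float(ortho[k]),
                allo_score=BUMPED if allo_bumped[k] else float(allo[k]),
                label=label,
                potency_band=band,
                ac50=a50,
            )
        )
    return records


def generate_kinetics(config: KineticsGenConfig) -> pd.DataFrame:
    """Simulate a long-format fluorescence plate from the mixed-inhibition
    model: fluorescence = scale · v(S, I) · lognormal noise, replicated
    n_tech × n_exp per (S, I). Deterministic given the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.noise_cv**2))  # lognormal with unit mean
    rows = []
    for s in config.substrate_concs:
        for i in config.inhibitor_concs:
            v = mixed_inhibition(
                np.asarray(s), np.asarray(i),
                config.v_max, config.k_m, config.k_i, config.alpha,
            )
            for exp_rep in range(1, config.n_exp + 1):
                for tech_rep in range(1, config.n_tech + 1):
                    noise = (
                        np.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
                    )
                    rows.append(
                        {
                            "inhibitor_conc": i,
                            "substrate_conc": s,
                            "tech_rep": tech_rep,
                            "exp_rep": exp_rep,
                            "fluorescence": float(config.scale * v * noise),
                        }
                    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ActivityGenConfig:
    """Screen activity-record generator: branch fractions of the curation
    scheme. Fractions apply sequentially to the remaining mass."""

    n: int = 200
    frac_single_conc_inactive: float = 0.55
    frac_constant: float = 0.20  # of dose–response tested compounds
    frac_ambiguous: float = 0.30  # of non-constant fits (high AC50 / low response)
    frac_missing_smiles: float = 0.02
    seed: int = 0


#: valid SMILES of ≥ 5 heavy atoms, cycled through generated records
_SMILES_POOL = (
    "c1ccccc1O", "CCCCCC", "CC(=O)Oc1ccccc1C(=O)O", "c1ccc2ccccc2c1",
    "CCN(CC)CC", "OC1CCCCC1", "Cc1ccc(O)cc1", "ClC(Cl)c1ccccc1",
)


def generate_activity_records(config: ActivityGenConfig) -> list[ActivityRecord]:
    """Draw raw screen records exercising every branch of the curation
    scheme (triage inactives, constant fits, ambiguous fits, inhibitors,
    invalid SMILES). Deterministic given the config."""
    rng = np.random.default_rng(config.seed)
    records = []
    for k in range(config.n):
        cid = f"ACT{k:05d}"
        smiles = (
            None
            if rng.random() < config.frac_missing_smiles
            else _SMILES_POOL[int(rng.integers(len(_SMILES_POOL)))]
        )
        if rng.random() < config.frac_single_conc_inactive:
            records.append(ActivityRecord(cid, smiles, single_conc_active=False))
            continue
        if rng.random() < config.frac_constant:
            records.append(
                ActivityRecord(cid, smiles, single_conc_active=True, fitted_model="constant")
            )
            continue
        if rng.random() < config.frac_ambiguous:
            # high AC50 or weak response — insufficient evidence either way
            if rng.random() < 0.5:
                rec = ActivityRecord(
                    cid, smiles, True, "non_constant",
                    ac50=float(10.0 ** rng.uniform(1.01, 3.0)), max_response=50.0,
                )
            else:
                rec = ActivityRecord(
                    cid, smiles, True, "non_constant",
                    ac50=float(10.0 ** rng.uniform(-1.0, 1.0)),
                    max_response=float(rng.uniform(0.0, 9.9)),
                )
            records.append(rec)
            continue
        records.append(
            ActivityRecord(
                cid, smiles, True, "non_constant",
                ac50=float(10.0 ** rng.uniform(-2.0, 1.0)),
                max_response=float(rng.uniform(20.0, 100.0)),
            )
        )
    return records
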