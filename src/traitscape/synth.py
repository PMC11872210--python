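"""Synthetic greenhouse and microsatellite populations.

This module generates the two kinds of input the analysis pipeline
consumes:

* pot-level trait tables for a full-factorial ramet experiment
  (donor individuals x water availability x CO2 level x replicate pots)
  with survival dropout and missing measurements, and
* clonal SSR genotype populations dominated by a single multilocus
  genotype, with low-frequency variants that gain or lose a few alleles.

The default parameter values emulate a greenhouse study of two
*Spartina* cytotypes (hybrid *S. x townsendii* and allopolyploid
*S. anglica*): 6 donor individuals x 2 water x 2 CO2 x 6 replicate pots
(144 pots), of which 21 die or senesce and 9 are removed for other
experiments, leaving 114 survivors for analysis.  One global integer
seed controls all randomness; each operation derives its own
deterministic sub-stream from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

WATER_LEVELS = ("well-watered", "drought")
CO2_LEVELS = ("ambient", "elevated")
CYTOTYPES = ("hybrid", "allopolyploid")

#: the six functional traits that span the trait-scape ordination
FUNCTIONAL_TRAITS = (
    "stomatal_length",   # um
    "root_shoot_ratio",  # g g^-1 (unitless)
    "leaf_area",         # mm^2
    "stem_height",       # cm
    "stem_diameter",     # mm
    "stem_density",      # stems per pot (count)
)
#: all measured responses (functional traits plus the fitness proxy)
ALL_TRAITS = FUNCTIONAL_TRAITS + ("biomass",)  # biomass in g

INTEGER_TRAITS = frozenset({"stem_density"})

DEFAULT_INDIVIDUALS = (
    ("H1", "hybrid"), ("H2", "hybrid"), ("H3", "hybrid"),
    ("A1", "allopolyploid"), ("A2", "allopolyploid"), ("A3", "allopolyploid"),
)

_ORIGINS = ("EWST", "tidal flat", "pioneer marsh", "low marsh",
            "high marsh", "tidal creek")

# fixed offsets used to derive independent per-operation RNG sub-streams
_STREAM_TRAITS = 15485863
_STREAM_SURVIVAL = 104729
_STREAM_MISSING = 32452843
_STREAM_SSR = 7919


class ConfigurationError(ValueError):
    """A model/design mismatch (e.g. a design cell without trait parameters)."""


class ValidationError(ValueError):
    """Invalid user input (counts, fractions, ranges)."""


@dataclass(frozen=True)
class DesignSpec:
    """Full-factorial greenhouse design.

    ``dropout`` is ``(n_dead, n_removed)``: pots that died/senesced
    during the experiment and pots removed for use elsewhere.  Both are
    excluded from analysis; the distinction is kept in the ``status``
    column of the generated table.
    """

    individuals: tuple[tuple[str, str], ...] = DEFAULT_INDIVIDUALS
    water_levels: tuple[str, ...] = WATER_LEVELS
    co2_levels: tuple[str, ...] = CO2_LEVELS
    replicates_per_cell: int = 6
    dropout: tuple[int, int] = (21, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise ValidationError("replicates_per_cell must be positive")
        n_dead, n_removed = self.dropout
        if n_dead < 0 or n_removed < 0:
            raise ValidationError("dropout counts must be non-negative")
        if n_dead + n_removed > self.n_pots:
            raise ValidationError(
                f"dropout ({n_dead}+{n_removed}) exceeds total pots ({self.n_pots})"
            )
        if not self.individuals:
            raise ValidationError("at least one individual is required")

    @property
    def n_pots(self) -> int:
        return (len(self.individuals) * len(self.water_levels)
                * len(self.co2_levels) * self.replicates_per_cell)

    @property
    def cells(self) -> list[tuple[str, str, str]]:
        """(cytotype, water, co2) combinations occurring in the design."""
        cytos = sorted({c for _, c in self.individuals})
        return [(cy, w, c) for cy in cytos
                for w in self.water_levels for c in self.co2_levels]


@dataclass
class TraitModel:
    """Per-cell trait distributions.

    ``cells`` maps ``(cytotype, water, co2)`` to ``{trait: (mean, sd)}``.
    Positive-valued traits are drawn from a normal truncated at zero;
    stem density is additionally rounded to a non-negative integer.
    ``missingness`` gives the completely-at-random missing rate per
    trait, applied to surviving pots only.
    """

    cells: Mapping[tuple[str, str, str], Mapping[str, tuple[float, float]]]
    missingness: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell, traits in self.cells.items():
            for trait, (mean, sd) in traits.items():
                if sd < 0:
                    raise ValidationError(f"SD < 0 for {trait} in cell {cell}")
                if mean <= 0:
                    raise ValidationError(
                        f"mean must be > 0 for positive trait {trait} in {cell}")
        for trait, rate in self.missingness.items():
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"missingness for {trait} not in [0, 1)")

    def traits(self) -> tuple[str, ...]:
        first = next(iter(self.cells.values()))
        return tuple(first)

    def sample(self, cell: tuple[str, str, str], trait: str, n: int,
               rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values of ``trait`` for a design cell."""
        try:
            mean, sd = self.cells[cell][trait]
        except KeyError as exc:
            raise ConfigurationError(f"model lacks {trait!r} for cell {cell}") from exc
        if sd == 0:
            values = np.full(n, float(mean))
        else:
            a = (0.0 - mean) / sd  # truncate at zero
            values = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                         size=n, random_state=rng)
        if trait in INTEGER_TRAITS:
            values = np.clip(np.rint(values), 0, None)
        return values


def default_trait_model() -> TraitModel:
    """Trait model anchored to the study's reported cell statistics.

    Stomatal length and biomass means/SDs are the reported values
    (hybrid 27.5 +/- 2.1 um vs. allopolyploid 38.2 +/- 3.0 um;
    well-watered biomass 13.8 +/- 6.3 g vs. 9.5 +/- 4.4 g, drought
    5.9 +/- 2.4 g vs. 5.0 +/- 1.8 g).  The remaining cells follow the
    qualitative cytotype contrasts (allopolyploid: fewer, thicker,
    taller stems and larger leaves; hybrid root:shoot peaking under
    well-watered x elevated CO2 and dropping under drought x elevated
    CO2) with field-realistic magnitudes; see docs/methods.md.
    """
    base = {
        "hybrid": {
            "stomatal_length": (27.5, 2.1),
            "root_shoot_ratio": (1.2, 0.35),
            "leaf_area": (900.0, 250.0),
            "stem_height": (55.0, 10.0),
            "stem_diameter": (2.5, 0.5),
            "stem_density": (20.0, 5.0),
        },
        "allopolyploid": {
            "stomatal_length": (38.2, 3.0),
            "root_shoot_ratio": (1.0, 0.30),
            "leaf_area": (1400.0, 350.0),
            "stem_height": (65.0, 12.0),
            "stem_diameter": (3.5, 0.6),
            "stem_density": (12.0, 4.0),
        },
    }
    biomass = {
        ("hybrid", "well-watered"): (13.8, 6.3),
        ("hybrid", "drought"): (5.9, 2.4),
        ("allopolyploid", "well-watered"): (9.5, 4.4),
        ("allopolyploid", "drought"): (5.0, 1.8),
    }
    cells: dict[tuple[str, str, str], dict[str, tuple[float, float]]] = {}
    for cyto in CYTOTYPES:
        for water in WATER_LEVELS:
            for co2 in CO2_LEVELS:
                params = dict(base[cyto])
                params["biomass"] = biomass[(cyto, water)]
                if water == "drought":
                    m, s = params["leaf_area"]
                    params["leaf_area"] = (0.80 * m, s)
                    m, s = params["stem_height"]
                    params["stem_height"] = (0.85 * m, s)
                    m, s = params["stem_density"]
                    params["stem_density"] = (0.80 * m, s)
                if cyto == "hybrid" and co2 == "elevated":
                    if water == "well-watered":
                        params["root_shoot_ratio"] = (1.5, 0.35)
                    else:
                        params["root_shoot_ratio"] = (0.9, 0.30)
                cells[(cyto, water, co2)] = params
    missingness = {trait: 0.02 for trait in FUNCTIONAL_TRAITS}
    missingness["stomatal_length"] = 0.05
    missingness["biomass"] = 0.0
    return TraitModel(cells=cells, missingness=missingness)


_WATER_CODE = {"well-watered": "WW", "drought": "DR"}
_CO2_CODE = {"ambient": "aCO2", "elevated": "eCO2"}


def generate_greenhouse(design: DesignSpec, model: TraitModel) -> pd.DataFrame:
    """Generate one record per pot of the full-factorial experiment.

    Returns a table with factor columns (``individual``, ``cytotype``,
    ``water``, ``co2``, ``replicate``), a ``status`` column
    (``survived`` / ``dead`` / ``removed``), a boolean ``survived``
    flag, and one column per modelled trait.  Dead and removed pots
    carry no measurements (NaN); missing values are injected completely
    at random among survivors at the model's per-trait rates.
    """
    for cell in design.cells:
        if cell not in model.cells:
            raise ConfigurationError(f"trait model lacks design cell {cell}")

    traits = model.traits()
    rows = []
    for ind, cyto in design.individuals:
        for water in design.water_levels:
            for co2 in design.co2_levels:
                for rep in range(1, design.replicates_per_cell + 1):
                    pot_id = f"{ind}-{_WATER_CODE.get(water, water)}-" \
                             f"{_CO2_CODE.get(co2, co2)}-r{rep}"
                    rows.append((pot_id, ind, cyto, water, co2, rep))
    df = pd.DataFrame(rows, columns=["pot_id", "individual", "cytotype",
                                     "water", "co2", "replicate"])
    n = len(df)

    # survival: dead/removed pots chosen uniformly at random
    n_dead, n_removed = design.dropout
    rng_surv = np.random.default_rng([design.seed, _STREAM_SURVIVAL])
    picked = rng_surv.choice(n, size=n_dead + n_removed, replace=False)
    status = np.full(n, "survived", dtype=object)
    status[picked[:n_dead]] = "dead"
    status[picked[n_dead:]] = "removed"
    df["status"] = status
    df["survived"] = df["status"] == "survived"

    # trait values drawn per design cell
    rng_traits = np.random.default_rng([design.seed, _STREAM_TRAITS])
    for trait in traits:
        df[trait] = np.nan
    for cell in design.cells:
        cyto, water, co2 = cell
        mask = ((df["cytotype"] == cyto) & (df["water"] == water)
                & (df["co2"] == co2)).to_numpy()
        k = int(mask.sum())
        if k == 0:
            continue
        for trait in traits:
            df.loc[mask, trait] = model.sample(cell, trait, k, rng_traits)

    # non-survivors were never measured
    df.loc[~df["survived"], list(traits)] = np.nan

    # missing completely at random among survivors
    rng_miss = np.random.default_rng([design.seed, _STREAM_MISSING])
    surv = df["survived"].to_numpy()
    for trait in traits:
        rate = model.missingness.get(trait, 0.0)
        if rate > 0:
            hit = rng_miss.random(n) < rate
            df.loc[surv & hit, trait] = np.nan
    return df


# ---------------------------------------------------------------------------
# SSR genotype synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSpec:
    """One microsatellite locus: its modal allele set and a pool of
    low-frequency alleles that variant samples may gain."""

    name: str
    modal: tuple[int, ...]
    rare: tuple[int, ...] = ()


#: Eight loci whose modal allele sets total 16 alleles, mirroring the
#: dominant multilocus genotype of the Wadden Sea population.
DEFAULT_LOCI = (
    LocusSpec("MS02", (268,), (257,)),
    LocusSpec("MS07", (257, 273), ()),
    LocusSpec("MS13", (248, 264), (238,)),
    LocusSpec("MS14", (271,), (260, 268)),
    LocusSpec("MS15", (223, 250, 258, 261), (242,)),
    LocusSpec("MS16", (204, 251, 260), ()),
    LocusSpec("MS17", (264, 273), ()),
    LocusSpec("MS18", (260,), (245, 250, 280, 288)),
)


def serialize_alleles(alleles) -> str:
    return "/".join(str(int(a)) for a in sorted(alleles))


def generate_ssr(n_samples: int,
                 loci: Sequence[LocusSpec] = DEFAULT_LOCI,
                 dominant_fraction: float = 0.557,
                 rare_allele_rate: float = 1.0,
                 hybrid_fraction: float = 7 / 79,
                 seed: int = 0) -> pd.DataFrame:
    """Generate a clonal SSR population.

    ``round(dominant_fraction * n_samples)`` samples carry the modal
    multilocus genotype exactly; of the remainder, a
    ``rare_allele_rate`` fraction deviate from it by gaining 1-4 rare
    alleles or losing 1-3 modal alleles (each variant drawn
    independently, so distinct variants may coincide).  With
    ``rare_allele_rate=0`` the population is a single genotype.

    Allele sets are serialized as slash-separated fragment sizes in bp
    (e.g. ``"223/250/258/261"``); an empty string denotes failed
    amplification at that locus.
    """
    if not loci:
        raise ValidationError("locus list must not be empty")
    if not 0.0 < dominant_fraction <= 1.0:
        raise ValidationError("dominant_fraction must be in (0, 1]")
    if not 0.0 <= rare_allele_rate <= 1.0:
        raise ValidationError("rare_allele_rate must be in [0, 1]")
    if n_samples < 1:
        raise ValidationError("n_samples must be positive")

    rng = np.random.default_rng([seed, _STREAM_SSR])

    if rare_allele_rate == 0.0:
        n_variants = 0
    else:
        n_modal = int(round(dominant_fraction * n_samples))
        n_variants = int(round(rare_allele_rate * (n_samples - n_modal)))
    variant_idx = set(rng.choice(n_samples, size=n_variants, replace=False).tolist())

    n_hybrid = int(round(hybrid_fraction * n_samples))
    n_hybrid = min(max(n_hybrid, 0), n_samples)
    hybrid_idx = set(rng.choice(n_samples, size=n_hybrid, replace=False).tolist())

    gain_pool = [(spec.name, a) for spec in loci for a in spec.rare]
    modal_pool = [(spec.name, a) for spec in loci for a in spec.modal]

    records = []
    for i in range(n_samples):
        alleles = {spec.name: set(spec.modal) for spec in loci}
        if i in variant_idx:
            can_lose = any(len(spec.modal) >= 2 for spec in loci)
            gain = bool(gain_pool) and (not can_lose or rng.random() < 0.5)
            if gain:
                k = min(int(rng.integers(1, 5)), len(gain_pool))
                for j in rng.choice(len(gain_pool), size=k, replace=False):
                    locus, a = gain_pool[j]
                    alleles[locus].add(a)
            else:
                # drop 1-3 alleles, never emptying a locus entirely
                # (a fully empty set would mimic failed amplification)
                k = int(rng.integers(1, 4))
                for _ in range(k):
                    candidates = [(spec.name, a) for spec in loci
                                  for a in sorted(alleles[spec.name])
                                  if len(alleles[spec.name]) >= 2]
                    if not candidates:
                        break
                    locus, a = candidates[int(rng.integers(0, len(candidates)))]
                    alleles[locus].discard(a)
        row = {
            "sample_id": f"S{i + 1:03d}",
            "cytotype": "hybrid" if i in hybrid_idx else "allopolyploid",
            "origin": _ORIGINS[int(rng.integers(0, len(_ORIGINS)))],
        }
        for spec in loci:
            row[spec.name] = serialize_alleles(alleles[spec.name])
        records.append(row)
    return pd.DataFrame.from_records(records)


def generate_leaves(n: int = 20, seed: int = 0, noise_sd: float = 0.0,
                    intercept: float | None = None,
                    slope: float | None = None) -> pd.DataFrame:
    """Generate leaf (width, length, area) calibration measurements.

    Areas follow the published *Spartina* leaf-area calibration
    ``area = 86 + 0.63224 * width * length`` unless other coefficients
    are given, plus optional Gaussian measurement noise.
    """
    from .allometry import LEAF_AREA_INTERCEPT, LEAF_AREA_SLOPE

    if n < 3:
        raise ValidationError("need at least 3 leaves")
    intercept = LEAF_AREA_INTERCEPT if intercept is None else intercept
    slope = LEAF_AREA_SLOPE if slope is None else slope
    rng = np.random.default_rng([seed, 2971])
    width = rng.uniform(4.0, 12.0, size=n)    # leaf width
    length = rng.uniform(100.0, 400.0, size=n)  # leaf length
    area = intercept + slope * width * length
    if noise_sd > 0:
        area = area + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"width": width, "length": length, "area": area})
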