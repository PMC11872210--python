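"""Shared fixtures: reference SSR populations and greenhouse tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from traitscape import (DesignSpec, DEFAULT_LOCI, TraitModel,
                        default_trait_model, generate_greenhouse)

# Published per-locus genotype-class carrier counts for the 79-sample
# Wadden Sea survey (7 hybrid, 72 allopolyploid samples):
# locus -> [(allele class, hybrid carriers, allopolyploid carriers), ...]
REFERENCE_LOCUS_CLASSES = {
    "MS02": [((268,), 7, 63), ((257, 268), 0, 9)],
    "MS07": [((257,), 1, 1), ((257, 273), 6, 71)],
    "MS13": [((248,), 0, 1), ((248, 264), 6, 67), ((238, 248, 264), 1, 4)],
    "MS14": [((271,), 7, 69), ((260, 271), 0, 2), ((268, 271), 0, 1)],
    "MS15": [((250,), 1, 0), ((223, 250, 261), 1, 5),
             ((223, 242, 250, 258), 0, 1), ((223, 250, 258, 261), 5, 66)],
    "MS16": [((204, 251, 260), 7, 72)],
    "MS17": [((264,), 0, 3), ((264, 273), 7, 69)],
    "MS18": [((260,), 7, 61), ((245, 260), 0, 1), ((245, 288), 0, 1),
             ((250, 260), 0, 7), ((260, 280), 0, 2)],
}


def build_reference_population() -> pd.DataFrame:
    """79-sample SSR table whose per-locus class counts equal the
    published survey's counts (the joint assignment across loci is
    arbitrary; per-locus marginals are what the frequency table uses)."""
    n_hybrid, n_allo = 7, 72
    cytotypes = ["hybrid"] * n_hybrid + ["allopolyploid"] * n_allo
    df = pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(79)],
        "cytotype": cytotypes,
        "origin": ["EWST"] * 79,
    })
    for locus, classes in REFERENCE_LOCUS_CLASSES.items():
        col = [""] * 79
        h_pos, a_pos = 0, n_hybrid
        for alleles, h_count, a_count in classes:
            serialized = "/".join(str(a) for a in sorted(alleles))
            for _ in range(h_count):
                col[h_pos] = serialized
                h_pos += 1
            for _ in range(a_count):
                col[a_pos] = serialized
                a_pos += 1
        assert h_pos == n_hybrid and a_pos == 79
        df[locus] = col
    return df


def build_modal_population() -> pd.DataFrame:
    """79 samples in which exactly 44 (3 hybrid + 41 allopolyploid)
    share the modal multilocus genotype; the rest are unique variants."""
    rows = []
    for i in range(79):
        hybrid = i < 7
        modal = (i < 3) or (7 <= i < 48)
        row = {"sample_id": f"S{i:03d}",
               "cytotype": "hybrid" if hybrid else "allopolyploid",
               "origin": "EWST"}
        for spec in DEFAULT_LOCI:
            alleles = set(spec.modal)
            if not modal and spec.name == "MS18":
                alleles.add(300 + i)  # unique private allele per variant
            row[spec.name] = "/".join(str(a) for a in sorted(alleles))
        rows.append(row)
    return pd.DataFrame.from_records(rows)


@pytest.fixture(scope="session")
def reference_population() -> pd.DataFrame:
    return build_reference_population()


@pytest.fixture(scope="session")
def modal_population() -> pd.DataFrame:
    return build_modal_population()


@pytest.fixture(scope="session")
def paper_design() -> DesignSpec:
    return DesignSpec(seed=11)


@pytest.fixture(scope="session")
def trait_model() -> TraitModel:
    return default_trait_model()


@pytest.fixture(scope="session")
def greenhouse(paper_design, trait_model) -> pd.DataFrame:
    return generate_greenhouse(paper_design, trait_model)


def zero_sd_model(model: TraitModel) -> TraitModel:
    """Copy of a trait model with all SDs zero and no missingness."""
    cells = {cell: {t: (m, 0.0) for t, (m, _) in traits.items()}
             for cell, traits in model.cells.items()}
    return TraitModel(cells=cells, missingness={})


def interaction_model() -> TraitModel:
    """Trait model with a pure cytotype x CO2 interaction: the
    allopolyploid shifts leaf area and stem height under elevated CO2,
    the hybrid has no CO2 response at all."""
    base = default_trait_model()
    cells = {}
    for (cyto, water, co2), traits in base.cells.items():
        params = dict(traits)
        params["root_shoot_ratio"] = (1.2, 0.35) if cyto == "hybrid" \
            else (1.0, 0.30)
        if cyto == "allopolyploid" and co2 == "elevated":
            m, s = params["leaf_area"]
            params["leaf_area"] = (m + 500.0, s)
            m, s = params["stem_height"]
            params["stem_height"] = (m + 15.0, s)
        cells[(cyto, water, co2)] = params
    return TraitModel(cells=cells, missingness={})
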