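"""Distance-based multivariate plasticity indices on trait-scape scores.

The multivariate plasticity index (MVPi) of a genotype is the mean
Euclidean distance, in the full k-dimensional PCA score space, over all
cross-environment pairs of its replicates: n replicates in the ambient
reference environment (well-watered, ambient CO2) against m replicates
in a treatment environment gives n*m pairwise distances, averaged.
Pairs within the same environment never enter the mean.

The plant trait variation index measures constitutive (ambient)
trait divergence: the mean distance of an individual's ambient
replicates to the centroid of *all* ambient replicates pooled across
individuals (the ordination origin when the scape was fitted on the
ambient set alone).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .scape import TraitScapePCA
from .synth import FUNCTIONAL_TRAITS

#: reference cell: the ambient environment of every contrast
AMBIENT_CELL = ("well-watered", "ambient")

_CELL_CODE = {
    ("well-watered", "ambient"): "WW-aCO2",
    ("well-watered", "elevated"): "WW-eCO2",
    ("drought", "ambient"): "DR-aCO2",
    ("drought", "elevated"): "DR-eCO2",
}

#: treatment cells contrasted against the ambient reference, plus the
#: CO2 contrast within the drought level
DEFAULT_CONTRASTS = (
    (("drought", "ambient"), AMBIENT_CELL),
    (("well-watered", "elevated"), AMBIENT_CELL),
    (("drought", "elevated"), AMBIENT_CELL),
    (("drought", "elevated"), ("drought", "ambient")),
)


def contrast_label(contrast) -> str:
    treat, ref = contrast
    return f"{_CELL_CODE.get(tuple(treat), treat)} vs {_CELL_CODE.get(tuple(ref), ref)}"


def euclidean_distance(x, y) -> float:
    """Plain Euclidean distance over all k score dimensions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def mvpi(ambient_scores, treatment_scores) -> float:
    """Mean Euclidean distance over all ambient x treatment replicate pairs."""
    A = np.atleast_2d(np.asarray(ambient_scores, dtype=float))
    T = np.atleast_2d(np.asarray(treatment_scores, dtype=float))
    if A.shape[0] < 1 or T.shape[0] < 1:
        raise ValueError("both replicate sets must be non-empty")
    if A.shape[1] != T.shape[1]:
        raise ValueError("score dimensionality mismatch")
    return float(cdist(A, T).mean())


def trait_variation_index(ambient_scores_by_individual: Mapping[str, np.ndarray]
                          ) -> dict[str, float]:
    """Mean distance of each individual's ambient replicates to the
    pooled ambient centroid."""
    if not ambient_scores_by_individual:
        raise ValueError("no individuals supplied")
    stacks = {ind: np.atleast_2d(np.asarray(rows, dtype=float))
              for ind, rows in ambient_scores_by_individual.items()}
    for ind, rows in stacks.items():
        if rows.shape[0] < 1:
            raise ValueError(f"individual {ind!r} has no ambient replicates")
    pooled = np.vstack(list(stacks.values()))
    centroid = pooled.mean(axis=0, keepdims=True)
    return {ind: float(cdist(rows, centroid).mean())
            for ind, rows in stacks.items()}


@dataclass
class PlasticityResult:
    """Per-group, per-contrast plasticity indices.

    ``ed_pairs`` lists every cross-environment replicate pair with its
    distance; ``indices`` holds the MVPi per (group, contrast) with the
    replicate counts n (ambient) and m (treatment) entering the mean.
    Groups lacking ambient replicates appear with MVPi = NaN.
    """

    ed_pairs: pd.DataFrame
    indices: pd.DataFrame
    group_by: str


def plasticity_by_contrast(scape: TraitScapePCA, records: pd.DataFrame,
                           contrasts: Sequence = DEFAULT_CONTRASTS,
                           group_by: str = "individual",
                           traits: Sequence[str] = FUNCTIONAL_TRAITS
                           ) -> PlasticityResult:
    """Assemble Euclidean-distance pairs and MVPi per group and contrast.

    ``records`` is a pot-level trait table (factor columns ``water``,
    ``co2``, ``individual``/``cytotype``, ``survived``); only surviving
    pots with complete trait values enter.  ``group_by`` chooses whether
    replicates are paired within donor individuals or pooled within
    cytotypes.
    """
    if group_by not in ("individual", "cytotype"):
        raise ValueError("group_by must be 'individual' or 'cytotype'")
    data = records[records["survived"]].copy() if "survived" in records else records.copy()
    if len(data) == 0:
        raise ValueError("no surviving records")
    X = data[list(traits)]
    if X.isna().any().any():
        raise ValueError("trait values contain missing entries; impute first")
    scores = np.asarray(scape.transform(X))
    data = data.reset_index(drop=True)

    pair_rows = []
    index_rows = []
    for group in sorted(data[group_by].unique()):
        gmask = (data[group_by] == group).to_numpy()
        for contrast in contrasts:
            (tw, tc), (rw, rc) = contrast
            label = contrast_label(contrast)
            ref_mask = gmask & (data["water"] == rw).to_numpy() \
                & (data["co2"] == rc).to_numpy()
            tr_mask = gmask & (data["water"] == tw).to_numpy() \
                & (data["co2"] == tc).to_numpy()
            n, m = int(ref_mask.sum()), int(tr_mask.sum())
            if n == 0 or m == 0:
                index_rows.append((group, label, np.nan, n, m))
                continue
            A = scores[ref_mask]
            T = scores[tr_mask]
            D = cdist(A, T)
            ref_ids = data.loc[ref_mask, "pot_id"] if "pot_id" in data else \
                pd.Series(np.where(ref_mask)[0])
            tr_ids = data.loc[tr_mask, "pot_id"] if "pot_id" in data else \
                pd.Series(np.where(tr_mask)[0])
            for i, xi in enumerate(ref_ids):
                for j, yj in enumerate(tr_ids):
                    pair_rows.append((group, label, xi, yj, float(D[i, j])))
            index_rows.append((group, label, float(D.mean()), n, m))
    ed_pairs = pd.DataFrame(pair_rows,
                            columns=["group", "contrast", "ambient_replicate",
                                     "treatment_replicate", "ed"])
    indices = pd.DataFrame(index_rows,
                           columns=["group", "contrast", "mvpi", "n", "m"])
    return PlasticityResult(ed_pairs=ed_pairs, indices=indices, group_by=group_by)


def ambient_scores_by_individual(scape: TraitScapePCA, records: pd.DataFrame,
                                 traits: Sequence[str] = FUNCTIONAL_TRAITS
                                 ) -> dict[str, np.ndarray]:
    """Extract per-individual ambient-environment score rows for the
    trait variation index."""
    data = records[records["survived"]] if "survived" in records else records
    amb = data[(data["water"] == AMBIENT_CELL[0])
               & (data["co2"] == AMBIENT_CELL[1])]
    if len(amb) == 0:
        raise ValueError("no ambient-environment records")
    X = amb[list(traits)]
    if X.isna().any().any():
        raise ValueError("trait values contain missing entries; impute first")
    scores = np.asarray(scape.transform(X))
    out = {}
    for ind in sorted(amb["individual"].unique()):
        out[ind] = scores[(amb["individual"] == ind).to_numpy()]
    return out
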