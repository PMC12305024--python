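"""Species-mean aggregation and ecological-axis construction by PCA.

PCA is on the correlation matrix (variables z-scored) because the inputs mix
units; components with eigenvalue >= 1 are retained and component signs are
fixed by orientation rules (e.g. canopy openness positive on axis 1, flight
height positive on axis 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: mimicry ring -> mimetic cluster
RING_TO_CLUSTER = {
    "eurimedia": "clearwing",
    "lerida": "clearwing",
    "aureliana": "clearwing",
    "agnosia": "clearwing",
    "hermias": "tiger-stripe",
    "mamercus": "tiger-stripe",
    "mothone": "tiger-stripe",
    "confusa": "confusa",
}

MIMICRY_RINGS = tuple(RING_TO_CLUSTER)
MIMETIC_CLUSTERS = ("clearwing", "tiger-stripe", "confusa")

#: default variable set entering the ecological-axis PCA
EC_VARIABLES = (
    "q_uv",
    "q_b",
    "q_lw",
    "flight_height_m",
    "canopy_openness_pct",
    "wing_area_mm2",
    "wing_aspect_ratio",
    "wing_loading_g_per_mm2",
)

#: default visual-system trait set (anatomical traits pre-log10 upstream)
VISUAL_TRAITS = (
    "red_facet_proportion",
    "eye_surface_area",
    "facet_number",
    "facet_diameter",
    "medulla_volume",
    "lobula_plate_volume",
    "lobula_volume",
    "rest_of_central_brain_volume",
)


class AxesError(ValueError):
    pass


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components (orthonormal columns)
    scores: pd.DataFrame  # observations x components
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    retained: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def species_means(
    records: pd.DataFrame, variables: list[str], species_col: str = "species"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arithmetic species means (pairwise missing exclusion) and per-cell n."""
    if species_col not in records.columns:
        raise AxesError(f"missing column {species_col!r}")
    missing = [v for v in variables if v not in records.columns]
    if missing:
        raise AxesError(f"missing variable column(s): {missing}")
    grp = records.groupby(species_col)[list(variables)]
    means = grp.mean()
    counts = grp.count()
    return means, counts


def pca_axes(
    table: pd.DataFrame,
    cutoff: float = 1.0,
    orientation: dict[int, tuple[str, int]] | None = None,
) -> PCAResult:
    """Correlation-matrix PCA of a species x variable table.

    ``orientation`` maps 0-based component index to (variable, sign): the
    loading of that variable on that component is forced to the given sign.
    Rows with missing cells are dropped with a warning.
    """
    if table.shape[1] < 2:
        raise AxesError("need at least two variables")
    complete = table.dropna()
    if len(complete) < len(table):
        dropped = sorted(set(table.index) - set(complete.index))
        log.warning("PCA dropped %d incomplete row(s): %s", len(dropped), dropped)
    if complete.shape[0] < 3:
        raise AxesError("need at least three complete rows")
    X = complete.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    const = [c for c, s in zip(complete.columns, sd) if s == 0]
    if const:
        raise AxesError(f"constant variable(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    if orientation:
        for comp, (var, sign) in orientation.items():
            if var not in complete.columns:
                raise AxesError(f"orientation variable {var!r} not in table")
            j = list(complete.columns).index(var)
            if np.sign(eigvec[j, comp]) != np.sign(sign) and eigvec[j, comp] != 0:
                eigvec[:, comp] *= -1
    comp_names = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=complete.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec, index=complete.index, columns=comp_names)
    explained = 100.0 * eigval / eigval.sum()
    retained = [c for c, ev in zip(comp_names, eigval) if ev >= cutoff]
    return PCAResult(loadings, scores, eigval, explained, retained)


def ecological_axes(
    table: pd.DataFrame,
    variables: tuple[str, ...] = EC_VARIABLES,
    cutoff: float = 1.0,
) -> PCAResult:
    """The EC1/EC2 PCA: light environment on axis 1, wing morphology on axis 2."""
    cols = [v for v in variables if v in table.columns]
    absent = set(variables) - set(cols)
    if absent:
        raise AxesError(f"missing EC variable(s): {sorted(absent)}")
    orientation = {0: ("canopy_openness_pct", +1), 1: ("flight_height_m", +1)}
    return pca_axes(table[cols], cutoff=cutoff, orientation=orientation)


def visual_trait_pca(
    table: pd.DataFrame,
    traits: tuple[str, ...] = VISUAL_TRAITS,
    cutoff: float = 1.0,
    orientation: dict[int, tuple[str, int]] | None = None,
) -> PCAResult:
    """Single-axis summary of visual-pathway traits.

    PC1 loadings are reported per trait so the allometric-control loading
    (rest of central brain volume) can be inspected against the others.
    """
    cols = [t for t in traits if t in table.columns]
    if len(cols) < 2:
        raise AxesError(f"need >= 2 visual traits, found {cols}")
    return pca_axes(table[cols], cutoff=cutoff, orientation=orientation)
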