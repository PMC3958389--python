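"""CSV input/output, the Box-Cox phenotype utility, and result writers.

File formats
------------
Cross file (CSV): one row per individual with columns ``id``, ``direction``
(F | Fprime | BC1..BC4), ``phenotype``, then one column per marker holding
``AA`` (P1/P1 homozygote), ``AB``, ``BB`` or ``NA``.  Marker columns must
match the map file's marker set and order.

Map file (CSV): columns ``chromosome``, ``marker``, ``position_cM`` with
strictly increasing positions per chromosome.  The female:male map ratio
``lambda`` is a run parameter, not stored in the file.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .design import EffectVector
from .linkage import DEFAULT_LAMBDA, GeneticMap
from .population import Population
from .simulate import SimulationScenario

__all__ = [
    "read_cross",
    "write_cross",
    "read_map",
    "write_map",
    "read_scenario",
    "boxcox_transform",
    "write_scan",
    "write_json",
]

log = logging.getLogger("cytoqtl")

_CODE_TO_TOKEN = {0: "AA", 1: "AB", 2: "BB", -1: "NA"}


def _atomic_write(path: str, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-cytoqtl-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_map(path: str, lam: float = DEFAULT_LAMBDA) -> GeneticMap:
    """Read a genetic map CSV; validates increasing positions per chromosome."""
    return GeneticMap.from_frame(pd.read_csv(path), lam=lam)


def write_map(gmap: GeneticMap, path: str) -> None:
    _atomic_write(path, gmap.to_frame().to_csv(index=False))


def read_cross(
    cross_path: str,
    map_path: str,
    lam: float = DEFAULT_LAMBDA,
    na_token: str = "NA",
) -> tuple[Population, GeneticMap]:
    """Read a cross CSV plus its map; returns a validated population.

    Unknown genotype tokens are treated as missing with a logged count.
    Raises on marker-set mismatch, mixed design families, or non-numeric
    phenotypes.
    """
    gmap = read_map(map_path, lam=lam)
    df = pd.read_csv(cross_path, dtype=str, keep_default_na=False)
    required = ["id", "direction", "phenotype"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cross file missing columns {missing_cols}")
    marker_cols = [c for c in df.columns if c not in required]
    if marker_cols != gmap.marker_names:
        raise ValueError(
            "cross-file marker columns do not match the map's marker order"
        )
    try:
        phenotype = pd.to_numeric(df["phenotype"]).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric phenotype values: {exc}") from exc

    token_map = {"AA": 0, "AB": 1, "BB": 2, na_token: -1}
    raw = df[marker_cols].to_numpy()
    geno = np.full(raw.shape, -1, dtype=np.int8)
    unknown = 0
    for token, code in token_map.items():
        geno[raw == token] = code
    known = np.isin(raw, list(token_map))
    unknown = int((~known).sum())
    if unknown:
        log.warning("read_cross: %d unknown genotype tokens set to missing", unknown)

    pop = Population(
        phenotype=phenotype,
        direction=df["direction"].to_numpy(dtype=object),
        genotypes=geno,
        marker_names=marker_cols,
        ids=df["id"].to_numpy(),
        meta={"n_unknown_tokens": unknown, "source": cross_path},
    )
    return pop, gmap


def write_cross(pop: Population, gmap: GeneticMap, cross_path: str,
                map_path: str | None = None) -> None:
    """Write a population (and optionally its map) in the cross CSV format."""
    df = pd.DataFrame({"id": pop.ids, "direction": pop.direction,
                       "phenotype": pop.phenotype})
    tokens = np.vectorize(_CODE_TO_TOKEN.get)(pop.genotypes)
    for j, name in enumerate(pop.marker_names):
        df[name] = tokens[:, j]
    _atomic_write(cross_path, df.to_csv(index=False))
    if map_path is not None:
        write_map(gmap, map_path)


def read_scenario(path: str) -> SimulationScenario:
    """Load a custom simulation scenario from a YAML file.

    The file holds the :class:`SimulationScenario` fields, with ``beta``
    given as a mapping of effect names (mu, c, a, d, i, ica, icd, ici);
    omitted effects default to zero.
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "beta" not in spec:
        raise ValueError("scenario YAML must be a mapping with a 'beta' entry")
    beta = EffectVector(**spec.pop("beta"))
    return SimulationScenario(beta=beta, **spec)


def boxcox_transform(y, lmbda: float | None = None, shift: float = 0.0):
    """Box-Cox power transform ((y^l - 1)/l, log at l=0) of a phenotype.

    When ``lmbda`` is not supplied it is chosen by profile likelihood over
    a fixed grid in [-2, 2].  Nonpositive values require an explicit
    ``shift`` (added to y first, and logged); constant input is an error.

    Returns ``(transformed, lmbda)``.
    """
    y = np.asarray(y, dtype=float)
    if shift:
        log.info("boxcox_transform: shifting phenotype by %+g", shift)
        y = y + shift
    if np.any(y <= 0):
        raise ValueError(
            "Box-Cox requires positive values; pass shift= to offset them"
        )
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype cannot be Box-Cox transformed")
    if lmbda is None:
        grid = np.linspace(-2.0, 2.0, 81)
        llf = [stats.boxcox_llf(l, y) for l in grid]
        lmbda = float(grid[int(np.argmax(llf))])
    return stats.boxcox(y, lmbda=lmbda), float(lmbda)


def write_scan(result, path: str) -> None:
    """Write a ScanResult as TSV (chromosome, position, LR, LOD, estimates)."""
    _atomic_write(path, result.to_frame().to_csv(sep="\t", index=False))


def write_json(obj, path: str) -> None:
    """Write a dict (or an object with .to_dict()) as JSON, atomically."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    _atomic_write(path, json.dumps(obj, indent=2, default=float) + "\n")
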