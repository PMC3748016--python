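"""CSV input/output for maps, genotypes, co-factors and results."""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from . import __version__
from .genome_map import GeneticMap, GenotypeData
from .liability import CofactorSpec

#: default genotype code dialect: file token -> internal class code
CODE_DIALECTS = {
    "123": {"1": 0, "2": 1, "3": 2},
    "AHB": {"A": 0, "H": 1, "B": 2},
}
MISSING_TOKENS = {"", "NA", "-", "nan"}


def read_map(path) -> GeneticMap:
    frame = pd.read_csv(path, comment="#")
    try:
        return GeneticMap.from_frame(frame)
    except ValueError as err:
        raise ValueError(f"malformed map file {path}: {err}") from err


def write_map(gmap: GeneticMap, path, **meta):
    _write_with_header(gmap.to_frame(), path, meta)


def read_genotypes(path, dialect: str = "123") -> GenotypeData:
    """Rows = individuals (first column ID), columns = markers."""
    frame = pd.read_csv(path, comment="#", dtype=str).fillna("NA")
    mapping = CODE_DIALECTS[dialect]
    ids = frame.iloc[:, 0].tolist()
    markers = list(frame.columns[1:])
    codes = np.empty((len(ids), len(markers)), dtype=int)
    for j, col in enumerate(markers):
        for i, tok in enumerate(frame[col].str.strip()):
            if tok in MISSING_TOKENS:
                codes[i, j] = -1
            elif tok in mapping:
                codes[i, j] = mapping[tok]
            else:
                raise ValueError(
                    f"malformed genotype file {path}: row {i + 2}, column {col!r}: "
                    f"unknown code {tok!r}"
                )
    return GenotypeData(ids, markers, codes=codes)


def write_genotypes(genotypes: GenotypeData, path, dialect: str = "123", **meta):
    inv = {v: k for k, v in CODE_DIALECTS[dialect].items()}
    inv[-1] = "NA"
    frame = pd.DataFrame(
        [[inv[c] for c in row] for row in genotypes.codes],
        columns=genotypes.marker_names,
    )
    frame.insert(0, "id", genotypes.individuals)
    _write_with_header(frame, path, meta)


def read_cofactors(path) -> list[CofactorSpec]:
    """Co-factor CSV: columns id, then one column per co-factor.

    A header comment line ``#spec <name> discrete phi1 phi2`` or
    ``#spec <name> continuous mu sigma2`` declares each co-factor's
    pre-selection distribution; columns without a declaration default to
    a balanced discrete factor.
    """
    specs_meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("#spec"):
                _, name, kind, p1, p2 = line.split()
                specs_meta[name] = (kind, float(p1), float(p2))
    frame = pd.read_csv(path, comment="#")
    specs = []
    for col in frame.columns[1:]:
        kind, p1, p2 = specs_meta.get(col, ("discrete", 0.5, 0.5))
        if kind == "discrete":
            specs.append(CofactorSpec(col, "discrete", values=frame[col].to_numpy(float),
                                      class_priors=(p1, p2)))
        else:
            specs.append(CofactorSpec(col, "continuous", values=frame[col].to_numpy(float),
                                      mu=p1, sigma2=p2))
    return specs


def write_cofactors(specs: list[CofactorSpec], individuals, path, **meta):
    frame = pd.DataFrame({"id": list(individuals)})
    lines = []
    for spec in specs:
        frame[spec.name] = spec.values
        if spec.kind == "discrete":
            lines.append(f"#spec {spec.name} discrete {spec.class_priors[0]} {spec.class_priors[1]}")
        else:
            lines.append(f"#spec {spec.name} continuous {spec.mu} {spec.sigma2}")
    _write_with_header(frame, path, meta, extra_lines=lines)


def write_results(frame: pd.DataFrame, path, **meta):
    _write_with_header(frame, path, meta)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_with_header(frame: pd.DataFrame, path, meta: dict, extra_lines=()):
    with open(path, "w") as fh:
        header = {"sdlmap": __version__, **meta}
        fh.write("# " + " ".join(f"{k}={v}" for k, v in header.items()) + "\n")
        for line in extra_lines:
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)
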