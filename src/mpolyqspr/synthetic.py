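"""Synthetic molecular graphs and property tables.

The generator emulates the statistical shape of the study's data: a few
dozen hydrogen-suppressed organic-like graphs (degree capped at 4, the
heavy-atom valence ceiling), their nine degree-based indices, a handful
of auxiliary continuous descriptors (boiling-point / dipole / infrared
analogues, generated as noisy monotone functions of molecular size and
therefore collinear with the indices, as in the real descriptor table),
and continuous targets built as declared combinations of index columns
plus Gaussian noise.  Missing cells and gross outliers can be injected at
configurable rates to exercise the preprocessing chain.

Because the generating coefficients are returned alongside the table,
parameter-recovery tests can check that the pipeline finds what was
planted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molgraph import MolecularGraph, from_edges
from .mpoly import INDEX_NAMES, all_indices

__all__ = [
    "SimulationConfig",
    "random_molecular_graph",
    "simulate_property_table",
    "AUX_DESCRIPTORS",
]

AUX_DESCRIPTORS = ("BP", "DE", "IR")

#: default target recipes: linear/nonlinear combinations of index columns,
#: loosely shaped like the magnitudes of the study's five properties
_DEFAULT_TARGETS: dict[str, dict[str, float]] = {
    "COM": {"M2": 8.0, "HM^2": 0.002},
    "MR": {"M1": 1.6, "GA": 1.2},
    "MV": {"M1": 2.4, "R": 6.0},
    "MW": {"M1": 3.4, "ABC": 2.0},
    "PO": {"M1": 0.35, "SCI": 1.1},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped generator settings.

    Defaults mirror the study conditions: 29 compounds (19 train + 10
    test in the source design), 8-30 heavy atoms, valence cap 4, noise at
    a few percent of each target's spread, no injected missingness or
    outliers unless asked for.
    """

    n_compounds: int = 29
    atoms_min: int = 8
    atoms_max: int = 30
    max_degree: int = 4
    targets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_TARGETS.items()}
    )
    noise_sd: dict[str, float] | float = 0.03  # fraction of target spread
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    n_noise_features: int = 0  # pure-noise decoy columns N1..Nk
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_degree < 2:
            raise ValueError("max_degree must be at least 2")
        if not 0 <= self.missing_rate < 1 or not 0 <= self.outlier_rate < 1:
            raise ValueError("missing_rate and outlier_rate must lie in [0, 1)")
        if isinstance(self.noise_sd, (int, float)) and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def random_molecular_graph(
    n_atoms: int, max_degree: int = 4, seed: int | np.random.Generator = 0
) -> MolecularGraph:
    """Random connected simple graph with every degree <= max_degree.

    Built as a random spanning tree (random-attachment, respecting the
    cap) plus extra edges added only where both endpoints stay within the
    cap.  Deterministic per seed.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    if max_degree < 2:
        raise ValueError("max_degree must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deg = np.zeros(n_atoms, dtype=int)
    edges: list[tuple[str, str]] = []
    for v in range(1, n_atoms):
        open_slots = np.flatnonzero(deg[:v] < max_degree)
        if len(open_slots) == 0:
            raise ValueError(
                f"cannot attach atom {v}: all earlier atoms at degree cap {max_degree}"
            )
        u = int(rng.choice(open_slots))
        edges.append((f"a{u}", f"a{v}"))
        deg[u] += 1
        deg[v] += 1
    # sprinkle ring-closing edges where the cap allows (~0.25 per atom)
    have = {frozenset(e) for e in edges}
    n_extra = rng.binomial(n_atoms, 0.25)
    for _ in range(n_extra):
        u, v = rng.integers(0, n_atoms, size=2)
        key = frozenset((f"a{u}", f"a{v}"))
        if u == v or key in have:
            continue
        if deg[u] < max_degree and deg[v] < max_degree:
            edges.append((f"a{u}", f"a{v}"))
            have.add(key)
            deg[u] += 1
            deg[v] += 1
    return from_edges(edges)


_TERM_RE = re.compile(r"^(?P<name>[A-Za-z][A-Za-z0-9]*)(\^(?P<power>\d+))?$")


def _eval_term(term: str, table: pd.DataFrame) -> pd.Series:
    m = _TERM_RE.match(term)
    if not m:
        raise ValueError(f"malformed target term {term!r} (expected NAME or NAME^k)")
    name = m.group("name")
    if name not in table.columns:
        raise ValueError(f"target term {term!r} references unknown index {name!r}")
    power = int(m.group("power") or 1)
    return table[name] ** power


def simulate_property_table(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Generate a property table and the ground truth that produced it.

    Returns ``(table, truth)`` where the table has columns: the nine
    indices, the auxiliary descriptors, then one column per configured
    target; and ``truth`` records the graphs' index values before
    corruption, the generating coefficient maps and the realized noise
    standard deviations.
    """
    rng = np.random.default_rng(cfg.seed)
    n_atoms = rng.integers(cfg.atoms_min, cfg.atoms_max + 1, size=cfg.n_compounds)
    graphs = {
        f"cmpd{i:03d}": random_molecular_graph(int(n), cfg.max_degree, rng)
        for i, n in enumerate(n_atoms)
    }
    idx = pd.DataFrame.from_dict(
        {cid: all_indices(g) for cid, g in graphs.items()}, orient="index"
    )[list(INDEX_NAMES)]
    idx.index.name = "id"

    size = idx["M1"]  # proxy for molecular size
    aux = pd.DataFrame(index=idx.index)
    # noisy monotone functions of size -> deliberately collinear descriptors
    aux["BP"] = 40.0 + 3.0 * size + rng.normal(0, 0.15 * size.std(), len(idx))
    aux["DE"] = 0.8 + 0.04 * size + rng.normal(0, 0.20 * (0.04 * size).std() + 0.05, len(idx))
    aux["IR"] = 600.0 + 9.0 * np.sqrt(size) + rng.normal(0, 4.0, len(idx))

    targets = pd.DataFrame(index=idx.index)
    noise_used: dict[str, float] = {}
    for tname, coeffs in cfg.targets.items():
        signal = sum(w * _eval_term(term, idx) for term, w in coeffs.items())
        signal = pd.Series(signal, index=idx.index)
        if isinstance(cfg.noise_sd, dict):
            frac = cfg.noise_sd.get(tname, 0.0)
        else:
            frac = float(cfg.noise_sd)
        sd = frac * float(signal.std(ddof=1)) if len(signal) > 1 else 0.0
        noise_used[tname] = sd
        targets[tname] = signal + rng.normal(0.0, sd, len(signal))

    # uninformative decoys: independent standard normals, for selection tests
    noise_feats = pd.DataFrame(
        rng.standard_normal((len(idx), cfg.n_noise_features)),
        index=idx.index,
        columns=[f"N{k+1}" for k in range(cfg.n_noise_features)],
    )
    table = pd.concat([idx, aux, noise_feats, targets], axis=1)
    feature_cols = list(INDEX_NAMES) + list(AUX_DESCRIPTORS) + list(noise_feats.columns)

    if cfg.outlier_rate > 0:
        mask = rng.random((len(table), len(feature_cols))) < cfg.outlier_rate
        vals = table[feature_cols].to_numpy()
        vals[mask] *= 12.0  # gross, unmistakable corruption
        table[feature_cols] = vals
    if cfg.missing_rate > 0:
        mask = rng.random((len(table), len(feature_cols))) < cfg.missing_rate
        vals = table[feature_cols].to_numpy()
        vals[mask] = np.nan
        table[feature_cols] = vals

    truth = {
        "indices": idx,
        "coefficients": {k: dict(v) for k, v in cfg.targets.items()},
        "noise_sd": noise_used,
        "feature_columns": feature_cols,
        "target_columns": list(cfg.targets),
        "graphs": graphs,
    }
    return table, truth
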