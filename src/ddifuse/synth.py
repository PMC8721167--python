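"""Synthetic datasets with planted latent-group structure.

Drugs belong to latent groups. Each feature source reserves a block of
descriptors per group; a drug's bits fire with probability ``p_in`` inside its
own group's block and ``p_out`` elsewhere, so within-group Jaccard similarity
exceeds between-group similarity by construction. ATC codes share their
leading hierarchy levels within a group, and the interaction type of a drug
pair is a deterministic function of the two groups, flipped to a uniformly
drawn other type with probability ``label_noise``.

One integer seed drives an independent named stream per artifact (groups,
each feature source, ATC, pair sampling, label noise), so e.g. changing
``pair_density`` never perturbs the feature draw.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .data import FEATURE_SOURCES, ATCTable, DDITable, DrugCatalog, FeatureMatrix


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic per-stream seed below 2**31."""
    return (int(seed) * 1000003 + zlib.crc32(name.encode())) % (2**31)


def stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, name))


@dataclass
class SynthConfig:
    """Generator settings; defaults are the bundled benchmark conditions."""

    m: int = 80
    n_groups: int = 4
    dims: tuple[int, ...] = (120, 100, 80, 40)  # struct, target, pathway, enzyme
    p_in: float = 0.5
    p_out: float = 0.02
    atc_match_depth: int = 4   # leading ATC levels shared within a group (of 5)
    n_types: int = 5
    type_rule: dict[tuple[int, int], int] | None = None  # group pair -> type
    label_noise: float = 0.05
    pair_density: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0.0 < self.pair_density <= 1.0:
            raise ValueError("pair_density must lie in (0, 1]")
        if len(self.dims) != len(FEATURE_SOURCES):
            raise ValueError(f"dims must give one width per source {FEATURE_SOURCES}")
        if not 1 <= self.atc_match_depth <= 5:
            raise ValueError("atc_match_depth must lie in 1..5")


@dataclass
class SynthDataset:
    """A generated dataset plus the ground-truth group assignment."""

    catalog: DrugCatalog
    features: dict[str, FeatureMatrix]
    atc: ATCTable
    ddis: DDITable
    groups: np.ndarray  # (m,) latent group per drug
    config: SynthConfig = field(repr=False, default=None)  # type: ignore[assignment]


def default_type_rule(n_groups: int, n_types: int) -> dict[tuple[int, int], int]:
    """Cyclic assignment of types to unordered group pairs (incl. same-group)."""
    rule = {}
    for t, (g, h) in enumerate(combinations_with_replacement(range(n_groups), 2)):
        rule[(g, h)] = t % n_types
    return rule


def _group_atc_bases(rng: np.random.Generator, n_groups: int) -> list[list[str]]:
    # distinct first letters ensure zero ATC similarity between groups at level 1
    letters = list(string.ascii_uppercase)
    first = rng.choice(letters, size=n_groups, replace=False)
    bases = []
    for g in range(n_groups):
        bases.append([
            str(first[g]),
            f"{rng.integers(100):02d}",
            str(rng.choice(letters)),
            str(rng.choice(letters)),
            f"{rng.integers(100):02d}",
        ])
    return bases


def _random_level(rng: np.random.Generator, level: int) -> str:
    if level in (1, 4):  # two-digit levels (indices 1 and 4)
        return f"{rng.integers(100):02d}"
    return str(rng.choice(list(string.ascii_uppercase)))


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Draw a full dataset (catalog, four feature spaces, ATC codes, DDIs)."""
    m, n_g = config.m, config.n_groups
    if n_g > 26:
        raise ValueError("at most 26 groups (distinct ATC first letters)")
    rule = config.type_rule or default_type_rule(n_g, config.n_types)
    for g, h in combinations_with_replacement(range(n_g), 2):
        key = (min(g, h), max(g, h))
        if key not in rule:
            raise ValueError(f"type_rule does not cover group pair {key}")
        if not 0 <= rule[key] < config.n_types:
            raise ValueError(f"type_rule maps {key} outside 0..{config.n_types - 1}")

    catalog = DrugCatalog(tuple(f"D{i:04d}" for i in range(m)))
    groups = stream(config.seed, "groups").permutation(np.arange(m) % n_g)

    features = {}
    for source, w in zip(FEATURE_SOURCES, config.dims):
        rng = stream(config.seed, f"features/{source}")
        block = w // n_g
        prob = np.full((m, w), config.p_out)
        for i in range(m):
            g = groups[i]
            prob[i, g * block:(g + 1) * block] = config.p_in
        values = (rng.random((m, w)) < prob).astype(np.int8)
        features[source] = FeatureMatrix(
            source, values,
            tuple(f"{source}_{j}" for j in range(w)), catalog.drug_ids,
        )

    rng = stream(config.seed, "atc")
    bases = _group_atc_bases(rng, n_g)
    entries = {}
    for i, drug in enumerate(catalog.drug_ids):
        levels = list(bases[groups[i]][: config.atc_match_depth])
        for lvl in range(config.atc_match_depth, 5):
            levels.append(_random_level(rng, lvl))
        entries[drug] = frozenset(["".join(levels)])
    atc = ATCTable(entries)

    rng = stream(config.seed, "pairs")
    all_pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    n_keep = max(1, round(config.pair_density * len(all_pairs)))
    chosen = rng.choice(len(all_pairs), size=n_keep, replace=False)
    chosen.sort()
    noise_rng = stream(config.seed, "noise")
    pairs = []
    for k in chosen:
        i, j = all_pairs[k]
        g, h = sorted((groups[i], groups[j]))
        t = rule[(g, h)]
        if config.label_noise > 0 and noise_rng.random() < config.label_noise:
            others = [u for u in range(config.n_types) if u != t]
            t = int(noise_rng.choice(others))
        pairs.append((catalog.drug_ids[i], catalog.drug_ids[j], int(t)))
    ddis = DDITable(pairs, tuple(f"type{t:02d}" for t in range(config.n_types)))

    return SynthDataset(catalog, features, atc, ddis, groups, config)
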