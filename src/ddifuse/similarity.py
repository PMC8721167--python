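"""Drug-drug similarity matrices.

Four feature spaces (chemical substructure, target, pathway, enzyme) are
compared with the Jaccard coefficient over their binary descriptor vectors;
the fifth similarity comes from the shared-prefix depth of WHO ATC codes in
their five-level hierarchy. Each output is symmetric, lies in [0, 1] and has
a unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ATC_PATTERN, ATCTable, DrugCatalog, FeatureMatrix

#: number of levels in the ATC hierarchy
ATC_LEVELS = 5


@dataclass
class SimilarityMatrix:
    source_name: str
    values: np.ndarray  # (m, m), symmetric, [0, 1], unit diagonal
    drug_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.drug_ids):
            raise ValueError("similarity matrix must be square on the catalog")
        self.values = v


def jaccard_similarity(features: FeatureMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard coefficient |f_i & f_j| / |f_i | f_j|.

    Two all-zero vectors get similarity 0 off-diagonal (absent annotation is
    not evidence of similarity); the diagonal is forced to 1.
    """
    f = np.asarray(features.values)
    if not np.isin(f, (0, 1)).all():
        raise ValueError("Jaccard similarity requires a binary feature matrix")
    f = f.astype(float)
    inter = f @ f.T
    counts = f.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(features.source_name, s, features.drug_ids)


def atc_code_similarity(code_a: str, code_b: str) -> float:
    """Shared-prefix depth of two ATC codes over the 5-level hierarchy (k/N)."""
    for code in (code_a, code_b):
        if not ATC_PATTERN.match(code):
            raise ValueError(f"malformed ATC code {code!r}")
    la = (code_a[0], code_a[1:3], code_a[3], code_a[4], code_a[5:7])
    lb = (code_b[0], code_b[1:3], code_b[3], code_b[4], code_b[5:7])
    k = 0
    for a, b in zip(la, lb):
        if a != b:
            break
        k += 1
    return k / ATC_LEVELS


def atc_similarity(atc: ATCTable, catalog: DrugCatalog) -> SimilarityMatrix:
    """ATC-hierarchy similarity; multiple codes aggregate by the maximum.

    Drugs without any ATC code are 0-similar to every other drug. The
    diagonal is forced to 1 regardless.
    """
    m = catalog.m
    code_sets = [sorted(atc.codes_for(d)) for d in catalog.drug_ids]
    s = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            best = 0.0
            for ca in code_sets[i]:
                for cb in code_sets[j]:
                    best = max(best, atc_code_similarity(ca, cb))
            s[i, j] = s[j, i] = best
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix("atc", s, catalog.drug_ids)


def build_all_similarities(
    features: dict[str, FeatureMatrix],
    atc: ATCTable | None,
    catalog: DrugCatalog,
) -> list[SimilarityMatrix]:
    """The five similarity matrices in fixed order (struct, target, pathway,
    enzyme, ATC); pass ``atc=None`` for the four-source variant."""
    from .data import FEATURE_SOURCES

    sims = []
    for source in FEATURE_SOURCES:
        fm = features[source]
        if fm.drug_ids != catalog.drug_ids:
            raise ValueError(f"feature matrix {source!r} is not on the catalog order")
        sims.append(jaccard_similarity(fm))
    if atc is not None:
        sims.append(atc_similarity(atc, catalog))
    return sims
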