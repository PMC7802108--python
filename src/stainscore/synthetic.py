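"""Synthetic staining atlases in the exact HPA table schema.

Real staining atlases have two salient structural features this generator
emulates: a *bimodal evaluation depth* (a handful of cell types scored for
nearly every protein, a long tail scored for very few) and a coupling
between scoring depth and detection (well-scored cell types accumulate far
more positive calls).  The default heterogeneous spec encodes both with
two cell-type classes; a single-class uniform spec is available for tests
that need i.i.d. structure.

Also provides the canonical pancreatic-enzyme worked-example fixture
(PRSS1/PNLIP/CELA3A + PRL) whose query yields staining scores 75 / 25 /
12.5 for the pancreas, pituitary and small-intestine cell types.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atlas_io import LEVELS, RELIABILITIES
from .errors import ConfigurationError

_LEVEL_ARRAY = np.array(LEVELS)
_RELIABILITY_ARRAY = np.array(RELIABILITIES)


@dataclasses.dataclass(frozen=True)
class CellClassSpec:
    """One class of cell types sharing coverage and staining behaviour.

    weight
        Fraction of cell-type keys assigned to this class.
    coverage
        Probability that any given gene is evaluated in a key of this class.
    level_probabilities
        Mean distribution over (High, Medium, Low, Not detected) for
        evaluated genes; each cell type draws its own distribution from a
        Dirichlet centred here.
    concentration
        Dirichlet concentration for the per-cell-type jitter (larger =
        cell types more alike).
    """

    weight: float
    coverage: float
    level_probabilities: tuple[float, float, float, float]
    concentration: float = 150.0


@dataclasses.dataclass(frozen=True)
class MarkerBlock:
    """A forced (gene set, cell-type key, level) assignment."""

    genes: tuple[str, ...]
    tissue: str
    cell_type: str
    level: str


@dataclasses.dataclass(frozen=True)
class AtlasSpec:
    """Shape and randomness of a generated atlas."""

    n_tissues: int = 45
    cells_per_tissue: int = 3
    n_genes: int = 1000
    classes: tuple[CellClassSpec, ...] = ()
    reliability_probabilities: tuple[float, float, float, float] = (0.25, 0.35, 0.30, 0.10)
    marker_blocks: tuple[MarkerBlock, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tissues, self.cells_per_tissue, self.n_genes) < 1:
            raise ConfigurationError("atlas dimensions must be positive")
        if abs(sum(self.reliability_probabilities) - 1.0) > 1e-9:
            raise ConfigurationError("reliability probabilities must sum to 1")
        for cls in self.classes:
            if abs(sum(cls.level_probabilities) - 1.0) > 1e-9:
                raise ConfigurationError("level probabilities must sum to 1")

    @property
    def n_keys(self) -> int:
        return self.n_tissues * self.cells_per_tissue


def heterogeneous_atlas_spec(seed: int = 0, **overrides) -> AtlasSpec:
    """The default two-class atlas used for the permutation null study.

    About a quarter of the 135 cell-type keys are "well scored" (almost
    every gene evaluated, richer staining); the rest are "seldom scored"
    (2% of genes evaluated, sparse staining) — mirroring the bimodal
    evaluation depth of real staining atlases, where seldom-scored cell
    types also contribute few positive calls.
    """
    classes = (
        CellClassSpec(weight=0.26, coverage=0.95, level_probabilities=(0.12, 0.18, 0.20, 0.50)),
        CellClassSpec(weight=0.74, coverage=0.02, level_probabilities=(0.01, 0.03, 0.06, 0.90)),
    )
    return AtlasSpec(classes=classes, seed=seed, **overrides)


def uniform_atlas_spec(
    seed: int = 0,
    coverage: float = 0.8,
    level_probabilities: tuple[float, float, float, float] = (0.10, 0.15, 0.15, 0.60),
    **overrides,
) -> AtlasSpec:
    """A single-class atlas: every cell type shares coverage and levels."""
    classes = (
        CellClassSpec(weight=1.0, coverage=coverage, level_probabilities=level_probabilities),
    )
    return AtlasSpec(classes=classes, seed=seed, **overrides)


def _gene_tables(n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    names = np.array([f"GENE{i + 1:04d}" for i in range(n_genes)])
    ids = np.array([f"SYNG{i + 1:011d}" for i in range(n_genes)])
    return names, ids


def generate_atlas(spec: AtlasSpec) -> pd.DataFrame:
    """Generate normal-tissue staining records, deterministic given the seed.

    Rows are sorted by (tissue, cell type, gene) so serialized output is
    byte-stable.  ``marker_blocks`` assignments appear verbatim, replacing
    any colliding generated record.
    """
    if not spec.classes:
        spec = dataclasses.replace(
            spec,
            classes=(
                CellClassSpec(
                    weight=1.0, coverage=0.8, level_probabilities=(0.10, 0.15, 0.15, 0.60)
                ),
            ),
        )
    rng = np.random.default_rng(spec.seed)
    gene_names, gene_ids = _gene_tables(spec.n_genes)

    keys = [
        (f"tissue {i + 1:02d}", f"cell type {c + 1}")
        for i in range(spec.n_tissues)
        for c in range(spec.cells_per_tissue)
    ]
    weights = np.array([c.weight for c in spec.classes], dtype=float)
    weights = weights / weights.sum()
    key_class = rng.choice(len(spec.classes), size=len(keys), p=weights)

    frames = []
    for (tissue, cell_type), ci in zip(keys, key_class):
        cls = spec.classes[ci]
        level_dist = rng.dirichlet(np.asarray(cls.level_probabilities) * cls.concentration)
        evaluated = np.flatnonzero(rng.random(spec.n_genes) < cls.coverage)
        if evaluated.size == 0:
            continue
        levels = _LEVEL_ARRAY[rng.choice(4, size=evaluated.size, p=level_dist)]
        rels = _RELIABILITY_ARRAY[
            rng.choice(4, size=evaluated.size, p=np.asarray(spec.reliability_probabilities))
        ]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids[evaluated],
                    "gene_name": gene_names[evaluated],
                    "tissue": tissue,
                    "cell_type": cell_type,
                    "level": levels,
                    "reliability": rels,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records = _apply_marker_blocks(records, spec, keys)
    return records.sort_values(
        ["tissue", "cell_type", "gene_name"], kind="mergesort"
    ).reset_index(drop=True)


def _apply_marker_blocks(records, spec: AtlasSpec, keys) -> pd.DataFrame:
    if not spec.marker_blocks:
        return records
    known = {(t.casefold(), c.casefold()) for t, c in keys}
    extra = []
    for block in spec.marker_blocks:
        if (block.tissue.casefold(), block.cell_type.casefold()) not in known:
            raise ConfigurationError(
                f"marker block references unknown key {block.tissue!r}/{block.cell_type!r}"
            )
        if block.level not in LEVELS:
            raise ConfigurationError(f"marker block level {block.level!r} not in {LEVELS}")
        collide = (
            records["gene_name"].isin(block.genes)
            & (records["tissue"].str.casefold() == block.tissue.casefold())
            & (records["cell_type"].str.casefold() == block.cell_type.casefold())
        )
        records = records[~collide]
        for gene in block.genes:
            extra.append(
                {
                    "gene_id": f"SYNM{abs(hash(gene)) % 10**9:09d}",
                    "gene_name": gene,
                    "tissue": block.tissue,
                    "cell_type": block.cell_type,
                    "level": block.level,
                    "reliability": "Supported",
                }
            )
    return pd.concat([records, pd.DataFrame(extra)], ignore_index=True)


def generate_cancer_atlas(
    spec: AtlasSpec, n_cancers: int = 20, patients_range: tuple[int, int] = (8, 12)
) -> pd.DataFrame:
    """Generate pathology-style per-patient count records.

    Each evaluated (gene, cancer) pair draws a patient total uniformly in
    ``patients_range`` and splits it multinomially over levels, so samples
    of the same cancer can disagree — the within-cancer heterogeneity
    characteristic of tumour staining.
    """
    if not spec.classes:
        raise ConfigurationError("spec needs at least one cell class")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    gene_names, gene_ids = _gene_tables(spec.n_genes)
    weights = np.array([c.weight for c in spec.classes], dtype=float)
    weights = weights / weights.sum()
    rows = []
    for ci_idx in range(n_cancers):
        cls = spec.classes[rng.choice(len(spec.classes), p=weights)]
        cancer = f"cancer type {ci_idx + 1:02d}"
        level_dist = rng.dirichlet(np.asarray(cls.level_probabilities) * cls.concentration)
        evaluated = np.flatnonzero(rng.random(spec.n_genes) < max(cls.coverage, 0.2))
        totals = rng.integers(patients_range[0], patients_range[1] + 1, size=evaluated.size)
        counts = np.array([rng.multinomial(n, level_dist) for n in totals])
        for gi, cnt in zip(evaluated, counts):
            rows.append(
                (gene_ids[gi], gene_names[gi], cancer, int(cnt[0]), int(cnt[1]), int(cnt[2]), int(cnt[3]))
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_name", "cancer", "n_high", "n_medium", "n_low", "n_not_detected"],
    )


#: Gene symbols of the worked example query.
WORKED_EXAMPLE_GENES = ("PRSS1", "PNLIP", "CELA3A", "PRL")

_WORKED_KEYS = (
    ("pancreas", "exocrine glandular cells"),
    ("pituitary gland", "cells in anterior"),
    ("small intestine", "glandular cells"),
)
_DISTRACTOR_KEYS = (
    ("liver", "hepatocytes"),
    ("lung", "pneumocytes"),
    ("skin", "keratinocytes"),
    ("colon", "glandular cells"),
    ("testis", "cells in seminiferous ducts"),
    ("kidney", "cells in tubules"),
)


def worked_example_fixture() -> pd.DataFrame:
    """The pancreatic-enzyme fixture behind the canonical 75 / 25 / 12.5 query.

    PRSS1, PNLIP and CELA3A stain High in pancreatic exocrine glandular
    cells; PRL stains High in pituitary anterior cells; PRSS1 stains
    Medium in small-intestine glandular cells.  All other cells of the
    grid — including six distractor cell types — are Not detected, the
    only completion of the unstated cells consistent with all three
    scores (t = 4 everywhere).  All records are rated Supported.
    """
    ids = {g: f"FIXG{i + 1:07d}" for i, g in enumerate(WORKED_EXAMPLE_GENES)}
    high = {
        _WORKED_KEYS[0]: {"PRSS1", "PNLIP", "CELA3A"},
        _WORKED_KEYS[1]: {"PRL"},
    }
    medium = {_WORKED_KEYS[2]: {"PRSS1"}}
    rows = []
    for key in _WORKED_KEYS + _DISTRACTOR_KEYS:
        tissue, cell_type = key
        for gene in WORKED_EXAMPLE_GENES:
            if gene in high.get(key, ()):
                level = "High"
            elif gene in medium.get(key, ()):
                level = "Medium"
            else:
                level = "Not detected"
            rows.append((ids[gene], gene, tissue, cell_type, level, "Supported"))
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "tissue", "cell_type", "level", "reliability"]
    )
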