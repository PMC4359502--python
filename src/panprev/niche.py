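"""Habitat-partitioned gene-family sets.

For each body-site niche label the pan-matrix yields four family sets:

* exclusively present — present in ≥ 1 genome of the niche and in no
  genome outside it (singletons of niche genomes qualify);
* exclusively absent — absent from every genome of the niche and present
  in every genome outside it;
* niche core — present in all genomes of the niche (reported as null for
  single-genome niches, where core and pan coincide trivially);
* niche pan — present in ≥ 1 genome of the niche.

Niche labels are free strings compared case-insensitively after trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .panmatrix import PanMatrix


@dataclass
class NicheSets:
    niche: str
    n_genomes: int
    exclusive_present: set[str]
    exclusive_absent: set[str]
    core: Optional[set[str]]  # None for single-genome niches
    pan: set[str]


@dataclass
class NicheReport:
    per_niche: dict[str, NicheSets]

    def counts_table(self) -> list[dict]:
        """Table-style count summary, one row per niche."""
        rows = []
        for niche, sets in sorted(self.per_niche.items()):
            rows.append(
                {
                    "niche": niche,
                    "genomes": sets.n_genomes,
                    "exclusive_present": len(sets.exclusive_present),
                    "exclusive_absent": len(sets.exclusive_absent),
                    "core": None if sets.core is None else len(sets.core),
                    "pan": len(sets.pan),
                }
            )
        return rows


def _norm(label: str) -> str:
    return label.strip().lower()


def _niche_columns(matrix: PanMatrix, niche: str) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (inside, outside) over the genome columns."""
    target = _norm(niche)
    known = {_norm(n) for n in matrix.niches.values()}
    if target not in known:
        raise ValueError(f"unknown niche label {niche!r}")
    inside = np.array(
        [_norm(matrix.niches[g]) == target for g in matrix.genomes], dtype=bool
    )
    return inside, ~inside


def exclusive_present(matrix: PanMatrix, niche: str) -> set[str]:
    """Families present only in genomes of ``niche``."""
    inside, outside = _niche_columns(matrix, niche)
    vals = matrix.values()
    mask = vals[:, inside].any(axis=1) & ~vals[:, outside].any(axis=1)
    return set(np.array(matrix.families)[mask])


def exclusive_absent(matrix: PanMatrix, niche: str) -> set[str]:
    """Families absent from all of ``niche`` but present in every other genome."""
    niche_labels = {_norm(n) for n in matrix.niches.values()}
    if len(niche_labels) < 2:
        raise ValueError(
            "exclusive absence is undefined for a single-niche collection"
        )
    inside, outside = _niche_columns(matrix, niche)
    vals = matrix.values()
    mask = ~vals[:, inside].any(axis=1) & vals[:, outside].all(axis=1)
    return set(np.array(matrix.families)[mask])


def niche_core_pan(
    matrix: PanMatrix, niche: str
) -> tuple[Optional[set[str]], set[str]]:
    """(niche core or None for single-genome niches, niche pan)."""
    inside, _ = _niche_columns(matrix, niche)
    if inside.sum() == 0:
        raise ValueError(f"niche {niche!r} has no genomes")
    vals = matrix.values()
    families = np.array(matrix.families)
    pan = set(families[vals[:, inside].any(axis=1)])
    if inside.sum() == 1:
        return None, pan
    core = set(families[vals[:, inside].all(axis=1)])
    return core, pan


def niche_report(matrix: PanMatrix) -> NicheReport:
    """All four family sets for every niche in the collection."""
    labels: dict[str, str] = {}
    for g in matrix.genomes:
        labels.setdefault(_norm(matrix.niches[g]), matrix.niches[g].strip())
    multi = len(labels) >= 2
    per_niche = {}
    for norm_label, display in sorted(labels.items()):
        core, pan = niche_core_pan(matrix, norm_label)
        per_niche[display] = NicheSets(
            niche=display,
            n_genomes=len(matrix.genomes_of_niche(norm_label)),
            exclusive_present=exclusive_present(matrix, norm_label),
            exclusive_absent=exclusive_absent(matrix, norm_label) if multi else set(),
            core=core,
            pan=pan,
        )
    return NicheReport(per_niche)


def heatmap_order(matrix: PanMatrix) -> list[str]:
    """Family order for presence/absence heatmap export.

    Families sorted by occupancy (descending row sum), then by the niche
    pattern of their carriers, then id — core block on top, niche blocks
    grouped, singletons last.
    """
    vals = matrix.values()
    families = matrix.families
    niches = [matrix.niches[g] for g in matrix.genomes]

    def key(i: int):
        carriers = sorted({_norm(niches[j]) for j in np.where(vals[i])[0]})
        return (-int(vals[i].sum()), tuple(carriers), families[i])

    return [families[i] for i in sorted(range(len(families)), key=key)]
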