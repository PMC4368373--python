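"""Bundled catalogue of mature miRNA sequences.

Three small tab-separated tables ship with the package:

* ``known_mirnas.tsv`` — mature plant miRNAs from conserved land-plant
  families (miR156 ... miR535) together with the liverwort sequences they
  matched, used as the default reference catalogue in tests and examples;
* ``novel_mirnas.tsv`` — the 42 putative liverwort (*Pellia endiviifolia*)
  miRNAs, with cluster mean counts;
* ``algal_homologs.tsv`` — liverwort miRNAs with homologous small RNAs in
  *Chlamydomonas reinhardtii* sequencing data, as sequence pairs.

A full-scale reference catalogue (e.g. a miRBase download) is supplied by
the user at run time; these tables are desk-scale fixtures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional

from .conserved import ReferenceMiRNA, base_family
from .io_preprocess import normalize_seq


@dataclass(frozen=True)
class NovelMiRNA:
    name: str
    seq: str
    mean_count: float
    note: str = ""

    @property
    def family(self) -> str:
        return base_family(self.name)

    @property
    def is_novel(self) -> bool:
        # pen-miR408-5p was re-identified as the star strand of a conserved
        # miRNA after precursor prediction and does not found a novel family.
        return self.note != "conserved_star"


@dataclass(frozen=True)
class AlgalHomologPair:
    name: str
    pen_seq: str
    algal_seq: str
    algal_label: str


def _rows(filename: str) -> List[Dict[str, str]]:
    ref = resources.files("penmir.data").joinpath(filename)
    with ref.open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_known_mirnas() -> List[ReferenceMiRNA]:
    out = []
    for row in _rows("known_mirnas.tsv"):
        species, _, fam = row["family"].partition("-")
        out.append(
            ReferenceMiRNA(
                family=row["family"],
                member=row["member"] or "",
                species=species,
                seq=normalize_seq(row["sequence"]),
            )
        )
    return out


def load_novel_mirnas() -> List[NovelMiRNA]:
    return [
        NovelMiRNA(
            name=row["name"],
            seq=normalize_seq(row["sequence"]),
            mean_count=float(row["mean_count"]),
            note=(row.get("note") or "").strip(),
        )
        for row in _rows("novel_mirnas.tsv")
    ]


def load_algal_homologs() -> List[AlgalHomologPair]:
    return [
        AlgalHomologPair(
            name=row["name"],
            pen_seq=normalize_seq(row["pen_sequence"]),
            algal_seq=normalize_seq(row["algal_sequence"]),
            algal_label=row["algal_label"],
        )
        for row in _rows("algal_homologs.tsv")
    ]


def get_novel(name: str) -> Optional[NovelMiRNA]:
    for m in load_novel_mirnas():
        if m.name == name:
            return m
    return None
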