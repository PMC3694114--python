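"""Bundled example data.

Small plain-text tables from a published androgen-stimulation study of
LNCaP prostate cancer cells, used in examples and validation:

- ``lncap_deseq_top10``: the top ten differentially expressed genes from a
  DESeq analysis of DHT-stimulated vs unstimulated LNCaP RNA-seq, with the
  tool's own ranking in the ``position`` column.
- ``lncap_annotation``: the genes' HG-U133A probeset annotations; three of
  the ten genes (GLYATL2, RP11-67L3.6, ERRFI1) have no HG-U133A probe and
  are absent from the file.
- ``cross_platform_stable_hits``: the 18 compounds that were significantly
  connected, with full perturbation stability, to both the RNA-seq-derived
  10-probe signature and the microarray-derived 23-probe signature, with
  their setsizes and both setscores.
"""

from importlib import resources

import pandas as pd

from .signature import AnnotationMap, DETable

__all__ = [
    "lncap_deseq_top10",
    "lncap_annotation",
    "cross_platform_stable_hits",
    "HGU133A_N",
]

# HG-U133A platform size: number of probesets, hence the signed-rank range
# of every reference profile built on that platform
HGU133A_N = 22_283


def _path(name: str):
    return resources.files("connmap.data").joinpath(name)


def lncap_deseq_top10() -> DETable:
    with resources.as_file(_path("lncap_deseq_top10.tsv")) as p:
        return DETable.read_tsv(p)


def lncap_annotation() -> AnnotationMap:
    with resources.as_file(_path("lncap_hgu133a_annotation.tsv")) as p:
        return AnnotationMap.read_tsv(p)


def cross_platform_stable_hits() -> pd.DataFrame:
    with resources.as_file(_path("cross_platform_stable_hits.tsv")) as p:
        return pd.read_csv(p, sep="\t")
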