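"""Canonical Desikan-Killiany cortical parcellation.

The 34 gyral-based regions per hemisphere, in FreeSurfer ``aparc`` spelling
and order (the order used by ``aparcstats2table``). This tuple is the single
source of truth for region naming throughout the package; readers normalize
incoming tables to this order.
"""

from __future__ import annotations

ATLAS_VERSION = "desikan-killiany/freesurfer-aparc/v1"

DESIKAN_KILLIANY_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

N_REGIONS = len(DESIKAN_KILLIANY_REGIONS)

assert N_REGIONS == 34
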