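"""Event class vocabulary shared across the pipeline.

A liquid-biopsy slide is imaged in four immunofluorescence channels:
DAPI (DNA), pan-cytokeratin (PanCK, epithelial), vimentin (VIM,
mesenchymal), and a shared CD45/CD31 channel (leukocyte/endothelial).
Nucleated (DAPI+) rare events are classified by the 2**3 combinations of
PanCK/VIM/CD45-CD31 positivity; anucleate DAPI- | PanCK+ particles in
the 1-10 um size range are large extracellular vesicles (LEVs).
"""

from __future__ import annotations

#: Fixed channel order used everywhere (TIFF pages, arrays, feature names).
CHANNELS: tuple[str, ...] = ("DAPI", "PanCK", "VIM", "CD45/CD31")

EPI_CTC = "epi.CTC"
MES_CTC = "mes.CTC"
DP_CTC = "dp.CTC"
TP_CTC = "tp.CTC"
VIM_CELL = "vim.cell"
HEM_CELL = "hem.cell"
VIM_HEM_CELL = "vim.hem.cell"
DAPI_ONLY = "dapi.only"
LEV = "LEV"
COMMON = "common"

#: The 8 nucleated rare classes, keyed by the (PanCK, VIM, CD45/CD31)
#: positivity triple. Exhaustive and mutually exclusive by construction.
RARE_CLASS_BY_TRIPLE: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): EPI_CTC,
    (True, True, False): MES_CTC,
    (True, False, True): DP_CTC,
    (True, True, True): TP_CTC,
    (False, True, False): VIM_CELL,
    (False, False, True): HEM_CELL,
    (False, True, True): VIM_HEM_CELL,
    (False, False, False): DAPI_ONLY,
}

#: Nucleated rare classes in canonical order.
NUCLEATED_RARE_CLASSES: tuple[str, ...] = (
    EPI_CTC, MES_CTC, DP_CTC, TP_CTC,
    VIM_CELL, HEM_CELL, VIM_HEM_CELL, DAPI_ONLY,
)

#: All classes that can be enumerated per ml (rare cells plus LEVs).
ENUMERATED_CLASSES: tuple[str, ...] = NUCLEATED_RARE_CLASSES + (LEV,)

#: Every label a detected event can carry.
ALL_LABELS: tuple[str, ...] = ENUMERATED_CLASSES + (COMMON,)

#: Cohort group names.
GROUPS: tuple[str, ...] = ("normal", "early", "late")
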