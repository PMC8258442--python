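"""Default cortical node sets.

Nodes are Desikan-atlas region labels in the ``{lh,rh}_<label>`` convention of
tabular surface-reconstruction exports.  Three networks are provided: a
left-hemisphere phonemic-fluency (PF) network centred on the Broca
(pars triangularis), Wernicke (banks of the superior temporal sulcus) and
supramarginal areas plus surrounding frontal/parietal/temporal cortex; a
left-hemisphere semantic network overlapping the PF set; and a 9-node right
frontoparietal executive-visuospatial network.

.. warning::
   These rosters are editable *data*, not fixed anatomy: the exact membership
   of published thickness-covariance networks varies between studies, and
   users with their own region lists should override these defaults through
   the pipeline configuration rather than rely on them verbatim.
"""

from __future__ import annotations

from .io import NodeSet

PF_LEFT = NodeSet.from_columns(
    "phonemic-fluency",
    [
        "lh_parstriangularis",
        "lh_parsopercularis",
        "lh_parsorbitalis",
        "lh_precentral",
        "lh_caudalmiddlefrontal",
        "lh_rostralmiddlefrontal",
        "lh_superiorfrontal",
        "lh_bankssts",
        "lh_supramarginal",
        "lh_inferiorparietal",
        "lh_superiortemporal",
        "lh_middletemporal",
        "lh_inferiortemporal",
        "lh_lingual",
        "lh_posteriorcingulate",
        "lh_rostralanteriorcingulate",
    ],
)

SEMANTIC_LEFT = NodeSet.from_columns(
    "semantic",
    [
        "lh_inferiortemporal",
        "lh_middletemporal",
        "lh_supramarginal",
        "lh_parstriangularis",
        "lh_parsopercularis",
        "lh_rostralmiddlefrontal",
        "lh_superiorfrontal",
        "lh_lateralorbitofrontal",
    ],
)

EXEC_VISUOSPATIAL_RIGHT = NodeSet.from_columns(
    "executive-visuospatial",
    [
        "rh_rostralmiddlefrontal",
        "rh_caudalmiddlefrontal",
        "rh_superiorfrontal",
        "rh_parstriangularis",
        "rh_supramarginal",
        "rh_superiorparietal",
        "rh_inferiorparietal",
        "rh_precuneus",
        "rh_lateraloccipital",
    ],
)

DEFAULT_NODE_SETS = {
    ns.name: ns for ns in (PF_LEFT, SEMANTIC_LEFT, EXEC_VISUOSPATIAL_RIGHT)
}
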