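"""Default ROI sets for the TLE atrophy pipeline.

The full morphometry table carries 12 subcortical volumes (mm^3) and 64
Desikan-Killiany-style cortical thickness values (mm), laterality encoded by
``Left_``/``Right_`` prefixes.  The 23-ROI modelling subset follows the
regions with the strongest mesial-TLE atrophy effects in large multi-site
morphometry studies (bilateral hippocampus and thalamus plus frontal,
temporal, parietal, occipital and cingulate cortices); the 13-feature map
merges its cortical members within lobes for the low-resolution stability
analysis.  Both lists are configuration defaults, not hard-coded anywhere in
the algorithms.
"""

SUBCORTICAL_BASE = [
    "Hippocampus",
    "Amygdala",
    "Caudate",
    "Accumbens",
    "Pallidum",
    "Thalamus",
]

# DK parcellation names, minus frontal pole and insula, 32 per hemisphere
CORTICAL_BASE = [
    "Bankssts",
    "Caudalanteriorcingulate",
    "Caudalmiddlefrontal",
    "Cuneus",
    "Entorhinal",
    "Fusiform",
    "Inferiorparietal",
    "Inferiortemporal",
    "Isthmuscingulate",
    "Lateraloccipital",
    "Lateralorbitofrontal",
    "Lingual",
    "Medialorbitofrontal",
    "Middletemporal",
    "Parahippocampal",
    "Paracentral",
    "Parsopercularis",
    "Parsorbitalis",
    "Parstriangularis",
    "Pericalcarine",
    "Postcentral",
    "Posteriorcingulate",
    "Precentral",
    "Precuneus",
    "Rostralanteriorcingulate",
    "Rostralmiddlefrontal",
    "Superiorfrontal",
    "Superiorparietal",
    "Superiortemporal",
    "Supramarginal",
    "Temporalpole",
    "Transversetemporal",
]


def _bilateral(names):
    return [f"{side}_{n}" for n in names for side in ("Left", "Right")]


SUBCORTICAL_ROIS = _bilateral(SUBCORTICAL_BASE)  # 12
CORTICAL_ROIS = _bilateral(CORTICAL_BASE)  # 64
ALL_ROIS = SUBCORTICAL_ROIS + CORTICAL_ROIS  # 76

#: default 23-ROI modelling subset
MODELING_ROIS = [
    "Left_Hippocampus",
    "Right_Hippocampus",
    "Left_Thalamus",
    "Right_Thalamus",
    "Left_Superiorfrontal",
    "Right_Superiorfrontal",
    "Left_Caudalmiddlefrontal",
    "Right_Caudalmiddlefrontal",
    "Left_Precentral",
    "Right_Precentral",
    "Left_Paracentral",
    "Left_Entorhinal",
    "Right_Entorhinal",
    "Left_Fusiform",
    "Right_Fusiform",
    "Left_Transversetemporal",
    "Right_Transversetemporal",
    "Left_Superiorparietal",
    "Right_Superiorparietal",
    "Left_Lateraloccipital",
    "Right_Lateraloccipital",
    "Left_Posteriorcingulate",
    "Right_Posteriorcingulate",
]

#: 23 -> 13 lobe-level merge of the modelling subset
LOBE_MERGE_MAP = {
    "Left_Hippocampus": ["Left_Hippocampus"],
    "Right_Hippocampus": ["Right_Hippocampus"],
    "Left_Thalamus": ["Left_Thalamus"],
    "Right_Thalamus": ["Right_Thalamus"],
    "Left_Frontal": [
        "Left_Superiorfrontal",
        "Left_Caudalmiddlefrontal",
        "Left_Precentral",
        "Left_Paracentral",
    ],
    "Right_Frontal": [
        "Right_Superiorfrontal",
        "Right_Caudalmiddlefrontal",
        "Right_Precentral",
    ],
    "Left_Temporal": [
        "Left_Entorhinal",
        "Left_Fusiform",
        "Left_Transversetemporal",
    ],
    "Right_Temporal": [
        "Right_Entorhinal",
        "Right_Fusiform",
        "Right_Transversetemporal",
    ],
    "Left_Parietal": ["Left_Superiorparietal"],
    "Right_Parietal": ["Right_Superiorparietal"],
    "Left_Occipital": ["Left_Lateraloccipital"],
    "Right_Occipital": ["Right_Lateraloccipital"],
    "Cingulate": ["Left_Posteriorcingulate", "Right_Posteriorcingulate"],
}

#: frontal cortical ROIs eligible to seed the cortex-predominant trajectory
FRONTAL_MODELING_ROIS = [
    "Left_Superiorfrontal",
    "Right_Superiorfrontal",
    "Left_Caudalmiddlefrontal",
    "Right_Caudalmiddlefrontal",
    "Left_Precentral",
    "Right_Precentral",
    "Left_Paracentral",
]


def is_volume_roi(name: str) -> bool:
    """Subcortical ROIs are volumes (mm^3); cortical ROIs are thickness (mm)."""
    return name in set(SUBCORTICAL_ROIS)
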