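"""Published cohort summary statistics shipped as simulator defaults.

Group-wise means and standard deviations of the three derived indices
(thickness in µm, attenuation coefficient in 1/µm, corrected intensity in
AU) for the macular RNFL and GCIPL, per quadrant and overall, in a cohort
of 38 pituitary-adenoma patients and 43 healthy controls.  These values
parameterise the default metrics-level cohort simulator and the published
ROC summaries used for internal-consistency checks.
"""

from __future__ import annotations

__all__ = [
    "LAYERS",
    "REGIONS",
    "INDICES",
    "N_PATIENTS",
    "N_CONTROLS",
    "GROUP_SUMMARY",
    "ROC_SUMMARY",
    "ROC_PAIRING",
]

LAYERS = ("RNFL", "GCIPL")
#: SN/IN/ST/IT are the superonasal, inferonasal, superotemporal and
#: inferotemporal quadrants of the fovea-centred 5-mm square; "average"
#: is the overall in-square mean.
REGIONS = ("SN", "IN", "ST", "IT", "average")
INDICES = ("thickness", "attenuation", "intensity")

N_PATIENTS = 38
N_CONTROLS = 43

#: ``GROUP_SUMMARY[(layer, region, index, group)] = (mean, sd)``.
GROUP_SUMMARY = {
    # --- RNFL thickness (µm)
    ("RNFL", "SN", "thickness", "patient"): (41.32, 5.67),
    ("RNFL", "SN", "thickness", "control"): (45.73, 4.61),
    ("RNFL", "IN", "thickness", "patient"): (43.37, 5.63),
    ("RNFL", "IN", "thickness", "control"): (49.86, 5.34),
    ("RNFL", "ST", "thickness", "patient"): (27.53, 3.02),
    ("RNFL", "ST", "thickness", "control"): (28.88, 2.50),
    ("RNFL", "IT", "thickness", "patient"): (29.47, 3.33),
    ("RNFL", "IT", "thickness", "control"): (31.24, 2.55),
    ("RNFL", "average", "thickness", "patient"): (35.44, 3.90),
    ("RNFL", "average", "thickness", "control"): (38.82, 3.07),
    # --- RNFL attenuation coefficient (1/µm)
    ("RNFL", "SN", "attenuation", "patient"): (0.00112, 0.00005),
    ("RNFL", "SN", "attenuation", "control"): (0.00125, 0.00017),
    ("RNFL", "IN", "attenuation", "patient"): (0.00112, 0.00006),
    ("RNFL", "IN", "attenuation", "control"): (0.00127, 0.00017),
    ("RNFL", "ST", "attenuation", "patient"): (0.00106, 0.00007),
    ("RNFL", "ST", "attenuation", "control"): (0.00118, 0.00017),
    ("RNFL", "IT", "attenuation", "patient"): (0.00105, 0.00007),
    ("RNFL", "IT", "attenuation", "control"): (0.00120, 0.00017),
    ("RNFL", "average", "attenuation", "patient"): (0.00109, 0.00005),
    ("RNFL", "average", "attenuation", "control"): (0.00122, 0.00016),
    # --- RNFL corrected intensity (AU)
    ("RNFL", "SN", "intensity", "patient"): (31023.94, 1287.96),
    ("RNFL", "SN", "intensity", "control"): (31358.52, 1215.93),
    ("RNFL", "IN", "intensity", "patient"): (30877.51, 1636.81),
    ("RNFL", "IN", "intensity", "control"): (31708.25, 1233.05),
    ("RNFL", "ST", "intensity", "patient"): (29176.80, 1759.36),
    ("RNFL", "ST", "intensity", "control"): (29030.85, 1308.46),
    ("RNFL", "IT", "intensity", "patient"): (29110.76, 1598.85),
    ("RNFL", "IT", "intensity", "control"): (29462.52, 1333.41),
    ("RNFL", "average", "intensity", "patient"): (30051.27, 1310.56),
    ("RNFL", "average", "intensity", "control"): (30381.26, 993.33),
    # --- GCIPL thickness (µm)
    ("GCIPL", "SN", "thickness", "patient"): (76.75, 8.21),
    ("GCIPL", "SN", "thickness", "control"): (79.56, 5.64),
    ("GCIPL", "IN", "thickness", "patient"): (73.37, 8.15),
    ("GCIPL", "IN", "thickness", "control"): (75.76, 6.18),
    ("GCIPL", "ST", "thickness", "patient"): (77.47, 6.65),
    ("GCIPL", "ST", "thickness", "control"): (77.80, 4.98),
    ("GCIPL", "IT", "thickness", "patient"): (77.90, 6.35),
    ("GCIPL", "IT", "thickness", "control"): (77.24, 6.01),
    ("GCIPL", "average", "thickness", "patient"): (76.37, 6.88),
    ("GCIPL", "average", "thickness", "control"): (77.76, 4.87),
    # --- GCIPL attenuation coefficient (1/µm)
    ("GCIPL", "SN", "attenuation", "patient"): (0.00108, 0.00006),
    ("GCIPL", "SN", "attenuation", "control"): (0.00121, 0.00018),
    ("GCIPL", "IN", "attenuation", "patient"): (0.00108, 0.00006),
    ("GCIPL", "IN", "attenuation", "control"): (0.00122, 0.00018),
    ("GCIPL", "ST", "attenuation", "patient"): (0.00105, 0.00008),
    ("GCIPL", "ST", "attenuation", "control"): (0.00121, 0.00019),
    ("GCIPL", "IT", "attenuation", "patient"): (0.00104, 0.00007),
    ("GCIPL", "IT", "attenuation", "control"): (0.00121, 0.00019),
    ("GCIPL", "average", "attenuation", "patient"): (0.00106, 0.00006),
    ("GCIPL", "average", "attenuation", "control"): (0.00121, 0.00018),
    # --- GCIPL corrected intensity (AU)
    ("GCIPL", "SN", "intensity", "patient"): (29767.34, 1535.41),
    ("GCIPL", "SN", "intensity", "control"): (30326.60, 1519.34),
    ("GCIPL", "IN", "intensity", "patient"): (29732.80, 1823.68),
    ("GCIPL", "IN", "intensity", "control"): (30609.55, 1619.45),
    ("GCIPL", "ST", "intensity", "patient"): (28940.98, 1935.87),
    ("GCIPL", "ST", "intensity", "control"): (29645.52, 1607.02),
    ("GCIPL", "IT", "intensity", "patient"): (28821.85, 1752.33),
    ("GCIPL", "IT", "intensity", "control"): (29708.56, 1656.98),
    ("GCIPL", "average", "intensity", "patient"): (29320.48, 1593.57),
    ("GCIPL", "average", "intensity", "control"): (30073.24, 1403.71),
}

#: Published per-index ROC summaries on the overall layer means:
#: ``ROC_SUMMARY[(layer, index)] = (auc, se, ci_low, ci_high)``.
ROC_SUMMARY = {
    ("RNFL", "thickness"): (0.764, 0.054, 0.659, 0.870),
    ("RNFL", "attenuation"): (0.751, 0.054, 0.645, 0.856),
    ("RNFL", "intensity"): (0.589, 0.064, 0.463, 0.715),
    ("GCIPL", "thickness"): (0.523, 0.066, 0.393, 0.653),
    ("GCIPL", "attenuation"): (0.758, 0.054, 0.652, 0.864),
    ("GCIPL", "intensity"): (0.639, 0.062, 0.518, 0.760),
}

#: The two significant indices whose AUCs are compared pairwise, per layer.
ROC_PAIRING = {
    "RNFL": ("thickness", "attenuation"),
    "GCIPL": ("attenuation", "intensity"),
}


def published_auc_difference(layer: str) -> float:
    """Difference between the published AUCs of the layer's paired indices."""
    a, b = ROC_PAIRING[layer]
    return round(ROC_SUMMARY[(layer, a)][0] - ROC_SUMMARY[(layer, b)][0], 3)
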