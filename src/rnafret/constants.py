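"""Experimental constants of the RNA end-to-end smFRET study.

These are the published study conditions: the dsDNA ruler set used to
calibrate the effective Forster radius, the dye-linker geometry, the eleven
mRNA constructs measured, the per-buffer linear trends of inter-dye distance
versus length, and the single-stranded RNA polymer parameters used to convert
end-to-end distances into exterior-loop contour lengths.
"""

import math

#: dsDNA ruler lengths used for calibration (base pairs).
RULER_LENGTHS_BP = (10, 13, 16, 19, 20, 21, 22, 25, 28, 45)

#: Helical rise of B-form dsDNA (nm per base pair).
RISE_PER_BP_NM = 0.34

#: Total effective dye-linker contribution when the two fluorophores point in
#: opposite directions (nm).
LINKER_TOTAL_NM = 1.5

#: Relative uncertainty of the dye-linker length.
LINKER_REL_UNCERTAINTY = 0.10

#: Effective Forster radius of the Alexa-546/Alexa-647 pair on this
#: instrument (nm), and its 1-sigma uncertainty.  R_eff absorbs the detection
#: factor gamma, so it is the only identifiable calibration parameter.
R_EFF_NM = 8.5
R_EFF_SIGMA_NM = 0.9

#: The eleven end-labelled mRNA constructs: (sample_id, length in nt,
#: cistron class).  Classes: mono(cistronic), di(cistronic), antisense.
TABLE1 = (
    ("fgen1-antisense", 574, "antisense"),
    ("fgen1", 574, "mono"),
    ("triat1", 1012, "mono"),
    ("chi18-4", 1667, "mono"),
    ("phr1", 2012, "mono"),
    ("BMV-RNA1", 3234, "mono"),
    ("BMV-RNA2", 2865, "mono"),
    ("CCMV-RNA2", 2774, "mono"),
    ("BMV-RNA3", 2117, "di"),
    ("CCMV-RNA3", 2177, "di"),
    ("BMV-RNA1+3", 5345, "di"),
)

TABLE1_LENGTHS_NT = tuple(row[1] for row in TABLE1)

#: Published linear fits distance = a + b * length per buffer condition.
#: TM: 10 mM Tris + 5 mM MgCl2; TE: magnesium-free.
TREND_FITS = {
    "TM": {"a": 6.8, "sigma_a": 0.47, "b": 7.2e-4, "sigma_b": 2e-4},
    "TE": {"a": 7.2, "sigma_a": 0.5, "b": 7.6e-4, "sigma_b": 2e-4},
}

#: Sample-to-sample scatter of the measured separations about the linear
#: trend (nm).
SCATTER_SD_NM = 1.2

#: Contour rise of single-stranded RNA (nm per nucleotide).
RISE_PER_NT_NM = 0.59

#: Persistence length of ssRNA at 5 mM MgCl2 (nm).
PERSISTENCE_LENGTH_SSRNA_NM = 2.1

#: Measured fluorophore-separation range across all constructs (nm),
#: and the corresponding 5'-3' end-to-end range after linker correction.
SEPARATION_RANGE_NM = (6.5, 10.5)
END_TO_END_RANGE_NM = (5.0, 9.0)

#: Conversion from a Gaussian sigma to full width at half maximum.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))
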