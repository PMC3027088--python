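"""Published reference values from the HyperGEN aortic-root-diameter study.

The HyperGEN African American cohort (Affymetrix 6.0 genotyping, sibship
ascertainment without genotyped parents) is the design this package's
simulator and pipeline emulate.  Two small published summaries are embedded
here as worked-example inputs:

* the family-size histogram of the genotyped cohort (421 families, 1,086
  individuals), which parameterises the default simulated roster;
* the top-ten association results of the two-stage aortic-root-diameter
  scan (stage-1 GRAMMAR screen p-values and stage-2 full-mixed-model
  p-values), used to exercise the genome-wide significance classification.

SNP effects are printed on the scale of 1e-3 ln(cm) per allele, standard
errors in parentheses in the source table; both are carried verbatim.
"""

from __future__ import annotations

import io as _io

import pandas as pd

#: Family-size histogram of the genotyped HyperGEN African American cohort:
#: size -> number of families.  Sums to 421 families / 1,086 individuals.
HYPERGEN_FAMILY_HISTOGRAM: dict[int, int] = {
    1: 99, 2: 160, 3: 69, 4: 48, 5: 23, 6: 10, 7: 8, 8: 0, 9: 3, 10: 1,
}

#: Cohort descriptives used as simulator defaults (means/sds/proportions).
HYPERGEN_DESCRIPTIVES: dict[str, float] = {
    "age_mean": 43.9,
    "age_sd": 13.4,
    "female_fraction": 0.666,
    "center_counts_AL": 856.0,
    "center_counts_NC": 230.0,
    "ard_mean_cm": 3.26,
    "ard_sd_cm": 0.38,
}

_TOP_MARKERS_TSV = """\
chrom	pos	marker_id	maf	stage1_p	snp_effect	snp_effect_se	stage2_p	genes
3	59877841	rs1825630	0.444	3.70e-5	9.46	2.11	7.99e-6	FHIT
7	65255030	rs875971	0.324	3.99e-5	10.69	2.24	4.09e-6	CRCP
7	65668047	rs801193	0.337	3.97e-5	11.13	2.23	3.65e-6	LOC401365,LOC493754
7	65700370	rs10258739	0.318	2.11e-5	10.64	2.26	2.50e-6	.
7	65733463	AFFX 9317457	0.332	6.24e-6	11.25	2.23	6.20e-7	KCTD7,RABGEF1
7	65733463	rs10263935	0.324	9.06e-6	11.42	2.28	4.26e-7	KCTD7,RABGEF1
7	65790536	rs2659915	0.334	4.10e-5	10.84	2.22	4.27e-6	RABGEF1
8	117625451	rs4876662	0.195	2.70e-5	13.17	2.58	2.23e-6	.
16	57316833	rs12600277	0.162	2.84e-5	13.99	2.98	2.72e-6	GOT2
20	1888504	rs6045666	0.351	3.21e-5	12.58	2.26	2.97e-6	SIRPA,PDYN
20	1889171	rs6045676	0.356	5.31e-7	11.47	2.28	3.28e-8	SIRPA,PDYN
"""


def load_reported_top_markers() -> pd.DataFrame:
    """Top-ten markers of the published two-stage aortic-root scan.

    Returns a DataFrame with stage-1 (GRAMMAR screen) and stage-2 (full mixed
    model) p-values as printed, suitable for
    :func:`cnvjoint.pipeline.flag_significance`.
    """
    df = pd.read_csv(_io.StringIO(_TOP_MARKERS_TSV), sep="\t", dtype={"chrom": str})
    return df
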