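"""Committed parameter set "default_reduced_v1" and the
wild-type limit-cycle snapshot used as the standard initial
condition.  Generated by the calibration pipeline: rates are
uniformly rescaled so the wild-type Per2 mRNA period is
exactly 23.8 h.  Units: vmax_*/basal_*/oe_* a.u./h;
deg_*/clr_*/seq_off_* 1/h; assoc_*/seq_on 1/(a.u. h);
K_* a.u.  Edit parameters through build_reduced_model
config overrides, not here."""

DEFAULT_PARAMS_REDUCED_V1 = {
    'K_act': 0.35,
    'K_rep_Bmal1': 0.6,
    'assoc_PER_CHRONO': 0.004445895406800943,
    'assoc_PER_CRY1': 0.004445895406800943,
    'assoc_PER_CRY2': 0.004445895406800943,
    'basal_Chrono': 0.008655602620115586,
    'basal_Cry1': 0.008655602620115586,
    'basal_Cry2': 0.008655602620115586,
    'basal_Per1': 0.008752856582139356,
    'basal_Per2': 0.008752856582139356,
    'basal_Rev': 0.0029176188607131183,
    'clr_C_CHR': 0.09030725045064415,
    'clr_C_PC1': 0.0382069136521956,
    'clr_C_PC2': 0.08266586772020502,
    'deg_A': 0.03473355786563236,
    'deg_CHRONO': 0.041680269438758834,
    'deg_CRY1': 0.03264954439369442,
    'deg_CRY2': 0.03264954439369442,
    'deg_M_Bmal1': 1.0420067359689709,
    'deg_M_Cry1': 0.14171291609178002,
    'deg_M_Cry2': 0.05557369258501178,
    'deg_M_Per1': 0.13893423146252945,
    'deg_M_Per2': 0.13893423146252945,
    'deg_M_Rev': 0.6946711573126473,
    'deg_PER': 0.2084013471937942,
    'deg_REV': 1.3893423146252946,
    'deg_R_CHR': 0.07988718309095444,
    'deg_R_PC1': 0.03473355786563236,
    'deg_R_PC2': 0.07085645804589001,
    'oe_default_Chrono': 0.10374502067939542,
    'oe_default_Cry1': 0.3729558808332773,
    'oe_default_Cry2': 1.3800902261745298,
    'oe_default_Per1': 0.7153001936526242,
    'oe_default_Per2': 0.7153001936526242,
    'seq_off_CHR': 0.11114738517002357,
    'seq_off_PC1': 0.03473355786563236,
    'seq_off_PC2': 0.09864330433839591,
    'seq_on': 91.69659276526944,
    'tl_Bmal1': 0.31260202079069127,
    'tl_Chrono': 0.13754488914790416,
    'tl_Cry1': 0.504331260208982,
    'tl_Cry2': 0.7335727421221555,
    'tl_Per': 0.9378060623720739,
    'tl_Rev': 1.0420067359689709,
    'vmax_Bmal1': 1.9450792404754123,
    'vmax_Chrono': 0.8655602620115586,
    'vmax_Cry1': 0.8655602620115586,
    'vmax_Cry2': 0.8655602620115586,
    'vmax_Per1': 0.8752856582139356,
    'vmax_Per2': 0.8752856582139356,
    'vmax_Rev': 0.29176188607131187,
}

# state on the wild-type limit cycle at the Per2 mRNA peak
DEFAULT_INITIAL_STATE = {
    'Per1_mRNA': float(1.5187844795922918),
    'Per2_mRNA': float(1.5187844795922918),
    'Cry1_mRNA': float(1.4867746581302776),
    'Cry2_mRNA': float(2.5927959426801754),
    'Chrono_mRNA': float(1.501909096485711),
    'Rev_mRNA': float(0.17325035854873),
    'Bmal1_mRNA': float(1.548205215472009),
    'PER@cyt': float(5.235302871858967),
    'CRY1@cyt': float(7.431381906766664),
    'CRY2@cyt': float(27.760119900949654),
    'CHRONO@cyt': float(1.7453723643660939),
    'REV@nuc': float(0.1367573736567476),
    'BMAL1_CLOCK@nuc': float(0.10941427675006005),
    'CRY1:PER@nuc': float(0.0241552197558689),
    'CRY2:PER@nuc': float(0.09758957279167252),
    'CHRONO:PER@nuc': float(0.006134045806735801),
    'BMAL1_CLOCK:CRY1:PER@nuc': float(3.075036834100315),
    'BMAL1_CLOCK:CRY2:PER@nuc': float(4.9203481386954016),
    'BMAL1_CLOCK:CHRONO:PER@nuc': float(0.27605672571543355),
}
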