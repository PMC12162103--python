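"""Independent, hand-written 24-equation right-hand side for the HNSCC TME
model, used as the oracle against the declarative edge-list assembler.

Every equation is spelled out explicitly from the rate laws; nothing here is
derived from the NetworkSpec machinery.
"""

import math

import numpy as np

# canonical state order
(
    C0_E, C0_P, CN_E, CN_P, CP_E, CP_P,
    TKP, TKN, THELP, TREG, TEX, M1, M2, FWT, CAF,
    IL2, IL8, IL10, LIF, IFNG, IRF8, OPN, ICAM1, LAC,
) = range(24)


def hnscc_reference_rhs(x, p, frozen_ia=None):
    """dx/dt of the HNSCC TME system, written out equation by equation.

    ``p`` is a mapping with the 91 registry keys.  States are assumed
    nonnegative (clipped like the production right-hand side).
    """
    xneg = np.minimum(x, 0.0)
    x = np.maximum(x, 0.0)
    dx = np.zeros(24)

    caf = x[CAF]
    ia = (1.0 - math.tanh(p["alpha_acc"] * p["Kbr"] * caf)
          if frozen_ia is None else frozen_ia)
    pen = math.exp(-p["alpha_acc"] ** 2 * p["delta"] * caf * caf)

    # accessibility-partitioned tumor carrying capacities
    ia_eff = max(ia, 1e-9)
    k_ia = p["xmax_tumor"] * ia_eff / (1.0 + ia_eff)
    k_fp = p["xmax_tumor"] / (1.0 + ia_eff)
    tot_e = x[C0_E] + x[CN_E] + x[CP_E]
    tot_p = x[C0_P] + x[CN_P] + x[CP_P]
    occ_e = min(tot_e / k_ia, 101.0)
    occ_p = min(tot_p / k_fp, 101.0)

    def hill(s, v):
        return s / (v + s)

    def para(kpara, alpha, s, v):
        return 1.0 + kpara * alpha * s / (v + s)

    # shared multipliers
    mult_tumor = (
        para(p["Kpara_CAF_tum"], p["alpha_CAF_tum"], caf, p["V_CAF_tum"])
        * para(p["Kpara_TEx_tum"], p["alpha_TEx_tum"], x[TEX], p["V_TEx_tum"])
    )
    mult_tk = (
        para(p["Kpara_IL2_TK"], p["alpha_IL2_TK"], x[IL2], p["V_IL2_TK"])
        * para(p["Kpara_THelp_TK"], p["alpha_THelp_TK"], x[THELP], p["V_THelp_TK"])
        * para(p["Kpara_IFNG_TK"], p["alpha_IFNG_TK"], x[IFNG], p["V_IFNG_TK"])
    )
    reg_lac = 1.0 / (p["Vreg_Lac_kill"] + p["alphareg_Lac_kill"] * x[LAC])
    reg_treg = 1.0 / (p["Vreg_TReg_THelp"] + p["alphareg_TReg_THelp"] * x[TREG])
    reg_irf8 = 1.0 / (p["Vreg_IRF8_OPN"] + p["alphareg_IRF8_OPN"] * x[IRF8])

    # conversions
    g_il8 = hill(x[IL8], p["V_conv_IL8"])
    g_ifng = hill(x[IFNG], p["V_conv_IFNG"])
    conv_c0_cn_e = p["Kconv_C0_Cn"] * x[C0_E] * g_il8
    conv_c0_cn_p = p["Kconv_C0_Cn"] * x[C0_P] * g_il8
    conv_cn_cp_e = p["Kconv_Cn_Cp"] * x[CN_E] * g_ifng
    conv_cn_cp_p = p["Kconv_Cn_Cp"] * x[CN_P] * g_ifng
    conv_fwt_caf = p["Kconv_FWT_CAF"] * x[FWT] * hill(x[LIF], p["V_conv_LIF"])
    conv_m1_m2 = p["Kconv_M1_M2"] * x[M1] * hill(x[IL10], p["V_conv_IL10"])
    conv_exh = (
        p["Kconv_exh"] * x[TKP]
        * hill(x[CP_E] + x[CP_P], p["V_exh"]) * hill(x[M2], p["V_exh"])
    )

    # killer-T elimination of exposed stem/PDL1- tumor cells (both killer
    # states), lactate-inhibited; the protected copies receive the
    # barrier-penetration leak
    killers = x[TKP] + x[TKN]
    kill_rate = p["Kkill"] * p["alpha_ac"] * reg_lac * killers
    kill_c0_e = kill_rate * x[C0_E]
    kill_cn_e = kill_rate * x[CN_E]
    kill_c0_p = kill_rate * pen * x[C0_P]
    kill_cn_p = kill_rate * pen * x[CN_P]

    # exposed <-> protected exchange
    mig = p["Kmig"]
    mig_c0 = mig * (1.0 - ia) * x[C0_E] - mig * ia * x[C0_P]
    mig_cn = mig * (1.0 - ia) * x[CN_E] - mig * ia * x[CN_P]
    mig_cp = mig * (1.0 - ia) * x[CP_E] - mig * ia * x[CP_P]

    kd_t = p["KD_tum"]
    dx[C0_E] = (p["Kprol_C0"] * x[C0_E] * (1.0 - occ_e) * mult_tumor
                - conv_c0_cn_e - kill_c0_e - kd_t * x[C0_E] - mig_c0)
    dx[C0_P] = (p["Kprol_C0"] * x[C0_P] * (1.0 - occ_p) * mult_tumor
                - conv_c0_cn_p - kill_c0_p - kd_t * x[C0_P] + mig_c0)
    dx[CN_E] = (p["Kprol_Cn"] * x[CN_E] * (1.0 - occ_e) * mult_tumor
                + conv_c0_cn_e - conv_cn_cp_e - kill_cn_e
                - kd_t * x[CN_E] - mig_cn)
    dx[CN_P] = (p["Kprol_Cn"] * x[CN_P] * (1.0 - occ_p) * mult_tumor
                + conv_c0_cn_p - conv_cn_cp_p - kill_cn_p
                - kd_t * x[CN_P] + mig_cn)
    dx[CP_E] = (p["Kprol_Cp"] * x[CP_E] * (1.0 - occ_e) * mult_tumor
                + conv_cn_cp_e - kd_t * x[CP_E] - mig_cp)
    dx[CP_P] = (p["Kprol_Cp"] * x[CP_P] * (1.0 - occ_p) * mult_tumor
                + conv_cn_cp_p - kd_t * x[CP_P] + mig_cp)

    dx[TKP] = (p["Kprol_TK"] * x[TKP] * (1.0 - x[TKP] / p["xmax_TK"]) * mult_tk
               - conv_exh - p["KD_TK"] * x[TKP])
    dx[TKN] = (p["Kprol_TK"] * x[TKN] * (1.0 - x[TKN] / p["xmax_TK"]) * mult_tk
               - p["KD_TK"] * x[TKN])
    dx[THELP] = (
        p["Kprol_THelp"] * x[THELP] * (1.0 - x[THELP] / p["xmax_THelp"])
        * para(p["Kpara_Cn_THelp"], p["alpha_Cn_THelp"],
               x[CN_E] + x[CN_P], p["V_Cn_THelp"])
        * reg_treg
        - p["KD_THelp"] * x[THELP]
    )
    dx[TREG] = (
        p["Kprol_TReg"] * x[TREG] * (1.0 - x[TREG] / p["xmax_TReg"])
        * para(p["Kpara_CAF_TReg"], p["alpha_CAF_TReg"], caf, p["V_CAF_TReg"])
        - p["KD_TReg"] * x[TREG]
    )
    dx[TEX] = (p["Kprol_TEx"] * x[TEX] * (1.0 - x[TEX] / p["xmax_TK"])
               + conv_exh - p["KD_TEx"] * x[TEX])
    dx[M1] = (p["Kprol_M1"] * x[M1] * (1.0 - x[M1] / p["xmax_M"])
              - conv_m1_m2 - p["KD_M1"] * x[M1])
    dx[M2] = (
        p["Kprol_M2"] * x[M2] * (1.0 - x[M2] / p["xmax_M"])
        * para(p["Kpara_CAF_M2"], p["alpha_CAF_M2"], caf, p["V_CAF_M2"])
        + conv_m1_m2 - p["KD_M2"] * x[M2]
    )
    dx[FWT] = (p["Kprol_FWT"] * x[FWT] * (1.0 - x[FWT] / p["xmax_fib"])
               - conv_fwt_caf - p["KD_FWT"] * x[FWT])
    dx[CAF] = (
        p["Kprol_CAF"] * caf * (1.0 - caf / p["xmax_fib"])
        * para(p["Kpara_OPN_CAF"], p["alpha_OPN_CAF"], x[OPN], p["V_OPN_CAF"])
        + conv_fwt_caf - p["KD_CAF"] * caf
    )

    tumor = tot_e + tot_p
    teff = x[TKP] + x[TKN] + x[THELP]
    tlymph = teff + x[TREG]
    kd_m = p["KD_mol"]
    dx[IL2] = p["Ksec_IL2_T"] * teff - kd_m * x[IL2]
    dx[IL8] = (p["Ksec_IL8_tum"] * tumor + p["Ksec_IL8_CAF"] * caf
               + p["Ksec_IL8_M2"] * x[M2] - kd_m * x[IL8])
    dx[IL10] = p["Ksec_IL10_T"] * tlymph - kd_m * x[IL10]
    dx[LIF] = (p["Ksec_LIF_tum"] * tumor + p["Ksec_LIF_FWT"] * x[FWT]
               - kd_m * x[LIF])
    dx[IFNG] = p["Ksec_IFNG_T"] * teff - kd_m * x[IFNG]
    dx[IRF8] = p["Ksec_IRF8_M1"] * x[M1] - kd_m * x[IRF8]
    dx[OPN] = (p["Ksec_OPN_tum"] * tumor * reg_irf8
               + p["Ksec_OPN_CAF"] * caf * reg_irf8 - kd_m * x[OPN])
    dx[ICAM1] = p["Ksec_ICAM1_T"] * teff - kd_m * x[ICAM1]
    dx[LAC] = p["Ksec_Lac_tum"] * tumor - kd_m * x[LAC]

    dx -= xneg  # same negative-excursion restoring term as production
    return dx
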