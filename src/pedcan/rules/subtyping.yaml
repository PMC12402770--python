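# Subtyping rule tables: label vocabulary, methylation-subclass mappings and
# gene lists consumed by pedcan.subtyping. Version: WHO-2021-aligned, v1.
version: 1

# Every label the engine may emit. The engine asserts membership.
labels:
  - "DMG, H3 K28"
  - "Oligodendroglioma, IDH-mutant"
  - "Oligosarcoma, IDH-mutant"
  - "PXA"
  - "DHG, H3 G35"
  - "HGG, IDH"
  - "HGG, H3 wild-type"
  - "HGG, To be classified"
  - "IHG, ALK-altered"
  - "IHG, NTRK-altered"
  - "IHG, ROS1-altered"
  - "IHG, MET-altered"
  - "IHG, To be classified"
  - "ATRT, MYC"
  - "ATRT, SHH"
  - "ATRT, TYR"
  - "ATRT, To be classified"
  - "NBL, MYCN amplified"
  - "NBL, MYCN non-amplified"
  - "NBL, To be classified"
  - "CRANIO, PAP"
  - "CRANIO, ADAM"
  - "CRANIO, To be classified"
  - "EPN, SP-MYCN"
  - "EPN, ST YAP1"
  - "EPN, ST ZFTA"
  - "EPN, PF A"
  - "EPN, PF B"
  - "EPN, MPE"
  - "EPN, PF SE"
  - "EPN, SP SE"
  - "EPN, SP"
  - "EPN, To be classified"
  - "LGG, other MAPK-altered"
  - "LGG, FGFR-altered"
  - "LGG, IDH-altered"
  - "LGG, MYB/MYBL1 fusion"
  - "LGG, MAPK-altered"
  - "LGG, BRAF- and MAPK-altered"
  - "SEGA, To be classified"
  - "LGG, To be classified"
  - "MB, SHH"
  - "MB, SHH alpha"
  - "MB, SHH beta"
  - "MB, SHH gamma"
  - "MB, SHH delta"
  - "MB, Group3"
  - "MB, Group4"
  - "MB, WNT"
  - "MB, MYO"
  - "MB, To be classified"
  - "PB, MYC/FOXR2-activated"
  - "PB, RB1-altered"
  - "PB, group 1"
  - "PB, group 2"
  - "PB, To be classified"
  - "ETMR, C19MC-altered"
  - "ETMR, NOS"
  - "ETMR, To be classified"

# Histone H3 genes whose K28M/K28I substitutions define H3 K28 alteration.
h3_k28_genes: [H3F3A, HIST1H3B, HIST1H3C, HIST2H3C]
h3_k28_changes: ["p.K28M", "p.K28I"]

# HGG methylation rules, evaluated in order; `contains` entries are matched
# as substrings of the subclass label, `equals` exactly.
hgg_methyl_rules:
  - {label: "DMG, H3 K28", contains: ["DMG"]}
  - {label: "Oligodendroglioma, IDH-mutant", equals: ["O_IDH"]}
  - {label: "Oligosarcoma, IDH-mutant", equals: ["OLIGOSARC_IDH"]}
  - {label: "DHG, H3 G35", equals: ["DHG_G34", "GBM_G34"]}
  - {label: "HGG, IDH", equals: ["A_IDH_HG", "GBM_IDH"]}
  - {label: "HGG, H3 wild-type",
     contains: ["GBM_MES", "GBM_RTK", "HGG_", "HGAP", "AAP", "ped_"]}

# IHG receptor-tyrosine-kinase fusion partners -> label.
ihg_rtk_map:
  ALK: "IHG, ALK-altered"
  NTRK1: "IHG, NTRK-altered"
  NTRK2: "IHG, NTRK-altered"
  NTRK3: "IHG, NTRK-altered"
  ROS1: "IHG, ROS1-altered"
  MET: "IHG, MET-altered"

atrt_map:
  ATRT_MYC: "ATRT, MYC"
  ATRT_SHH: "ATRT, SHH"
  ATRT_TYR: "ATRT, TYR"

# Craniopharyngioma: substring match on the methylation subclass.
cranio_contains_map:
  CPH_PAP: "CRANIO, PAP"
  CPH_ADM: "CRANIO, ADAM"

lgg_map:
  PA_MID: "LGG, other MAPK-altered"
  PLNTY: "LGG, other MAPK-altered"
  PA_INF_FGFR: "LGG, FGFR-altered"
  A_IDH_LG: "LGG, IDH-altered"
  AG_MYB: "LGG, MYB/MYBL1 fusion"
  LGG_MYB: "LGG, MYB/MYBL1 fusion"
  "LGG, MAPK": "LGG, MAPK-altered"
  "LGG, BRAF/MAPK": "LGG, BRAF- and MAPK-altered"
  "SEGA, To be classified": "SEGA, To be classified"

mb_group_map:
  MB_G34_I: "MB, Group3"
  MB_G34_II: "MB, Group3"
  MB_G34_III: "MB, Group3"
  MB_G34_IV: "MB, Group3"
  MB_G34_V: "MB, Group4"
  MB_G34_VI: "MB, Group4"
  MB_G34_VII: "MB, Group4"
  MB_G34_VIII: "MB, Group4"
  MB_WNT: "MB, WNT"
  MB_MYO: "MB, MYO"

# Methylation subclass -> consensus group for the RNA-vs-methylation
# concordance comparison (MB_SHH_* handled by prefix in code).
mb_concordance_map:
  MB_G34_I: Group3
  MB_G34_II: Group3
  MB_G34_III: Group3
  MB_G34_IV: Group3
  MB_G34_V: Group4
  MB_G34_VI: Group4
  MB_G34_VII: Group4
  MB_G34_VIII: Group4
  MB_WNT: WNT
  MB_MYO: MYO

mb_shh_map:
  MB_SHH_3: "MB, SHH alpha"
  MB_SHH_1: "MB, SHH beta"
  MB_SHH_2: "MB, SHH gamma"
  MB_SHH_4: "MB, SHH delta"

pb_map:
  PB_FOXR2: "PB, MYC/FOXR2-activated"
  PB_RB1: "PB, RB1-altered"
  PB_GRP1A: "PB, group 1"
  PB_GRP1B: "PB, group 1"
  PB_GRP2: "PB, group 2"

# EPN methylation subclasses that map directly to their own label.
epn_methyl_labels:
  ["EPN, SP-MYCN", "EPN, ST YAP1", "EPN, ST ZFTA", "EPN, PF A", "EPN, PF B",
   "EPN, MPE", "EPN, PF SE", "EPN, SP SE", "EPN, SP"]

epn_yap1_fusions: ["YAP1::MAMLD1", "YAP1::MAML2", "YAP1::FAM118B"]
epn_zfta_fusions: ["ZFTA::RELA", "ZFTA::MAML2"]
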