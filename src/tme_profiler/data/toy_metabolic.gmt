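OXPHOS	toy oxidative phosphorylation set matching the synthetic gene universe	OXPHOS_01	OXPHOS_02	OXPHOS_03	OXPHOS_04	OXPHOS_05	OXPHOS_06	OXPHOS_07	OXPHOS_08	OXPHOS_09	OXPHOS_10	OXPHOS_11	OXPHOS_12	OXPHOS_13	OXPHOS_14	OXPHOS_15	OXPHOS_16	OXPHOS_17	OXPHOS_18	OXPHOS_19	OXPHOS_20
TCA	toy TCA cycle set matching the synthetic gene universe	TCA_01	TCA_02	TCA_03	TCA_04	TCA_05	TCA_06	TCA_07	TCA_08	TCA_09	TCA_10	TCA_11	TCA_12	TCA_13	TCA_14	TCA_15
GLYC	toy glycolysis/gluconeogenesis set matching the synthetic gene universe	GLYC_01	GLYC_02	GLYC_03	GLYC_04	GLYC_05	GLYC_06	GLYC_07	GLYC_08	GLYC_09	GLYC_10	GLYC_11	GLYC_12	GLYC_13	GLYC_14	GLYC_15
ANGIOGENESIS	toy angiogenesis hallmark set matching the synthetic gene universe	ANGIO_01	ANGIO_02	ANGIO_03	ANGIO_04	ANGIO_05	ANGIO_06	ANGIO_07	ANGIO_08	ANGIO_09	ANGIO_10	ANGIO_11	ANGIO_12	ANGIO_13	ANGIO_14	ANGIO_15	ANGIO_16	ANGIO_17	ANGIO_18	ANGIO_19	ANGIO_20
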