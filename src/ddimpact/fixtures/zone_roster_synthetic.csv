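zone_id,province,arm
gombe_matadi,KONGO_CENTRAL,PRO_DS
kisantu,KONGO_CENTRAL,PRO_DS
ngidinga,KONGO_CENTRAL,PRO_DS
kc_non_01,KONGO_CENTRAL,NON_PRO_DS
kc_non_02,KONGO_CENTRAL,NON_PRO_DS
kc_non_03,KONGO_CENTRAL,NON_PRO_DS
kc_non_04,KONGO_CENTRAL,NON_PRO_DS
kc_non_05,KONGO_CENTRAL,NON_PRO_DS
kc_non_06,KONGO_CENTRAL,NON_PRO_DS
kc_non_07,KONGO_CENTRAL,NON_PRO_DS
kc_non_08,KONGO_CENTRAL,NON_PRO_DS
kc_non_09,KONGO_CENTRAL,NON_PRO_DS
kc_non_10,KONGO_CENTRAL,NON_PRO_DS
kc_non_11,KONGO_CENTRAL,NON_PRO_DS
kc_non_12,KONGO_CENTRAL,NON_PRO_DS
kc_non_13,KONGO_CENTRAL,NON_PRO_DS
kc_non_14,KONGO_CENTRAL,NON_PRO_DS
kc_non_15,KONGO_CENTRAL,NON_PRO_DS
kc_non_16,KONGO_CENTRAL,NON_PRO_DS
kc_non_17,KONGO_CENTRAL,NON_PRO_DS
kc_non_18,KONGO_CENTRAL,NON_PRO_DS
kc_non_19,KONGO_CENTRAL,NON_PRO_DS
kc_non_20,KONGO_CENTRAL,NON_PRO_DS
kc_non_21,KONGO_CENTRAL,NON_PRO_DS
kc_non_22,KONGO_CENTRAL,NON_PRO_DS
kc_non_23,KONGO_CENTRAL,NON_PRO_DS
kc_non_24,KONGO_CENTRAL,NON_PRO_DS
kc_non_25,KONGO_CENTRAL,NON_PRO_DS
kc_non_26,KONGO_CENTRAL,NON_PRO_DS
kc_non_27,KONGO_CENTRAL,NON_PRO_DS
kc_non_28,KONGO_CENTRAL,NON_PRO_DS
bunia,ITURI,PRO_DS
nyankunde,ITURI,PRO_DS
komanda,ITURI,PRO_DS
mambasa,ITURI,PRO_DS
tchomia,ITURI,PRO_DS
nizi,ITURI,PRO_DS
drodro,ITURI,PRO_DS
it_non_01,ITURI,NON_PRO_DS
it_non_02,ITURI,NON_PRO_DS
it_non_03,ITURI,NON_PRO_DS
it_non_04,ITURI,NON_PRO_DS
it_non_05,ITURI,NON_PRO_DS
it_non_06,ITURI,NON_PRO_DS
it_non_07,ITURI,NON_PRO_DS
it_non_08,ITURI,NON_PRO_DS
it_non_09,ITURI,NON_PRO_DS
it_non_10,ITURI,NON_PRO_DS
it_non_11,ITURI,NON_PRO_DS
it_non_12,ITURI,NON_PRO_DS
it_non_13,ITURI,NON_PRO_DS
it_non_14,ITURI,NON_PRO_DS
it_non_15,ITURI,NON_PRO_DS
it_non_16,ITURI,NON_PRO_DS
it_non_17,ITURI,NON_PRO_DS
it_non_18,ITURI,NON_PRO_DS
it_non_19,ITURI,NON_PRO_DS
it_non_20,ITURI,NON_PRO_DS
it_non_21,ITURI,NON_PRO_DS
it_non_22,ITURI,NON_PRO_DS
it_non_23,ITURI,NON_PRO_DS
it_non_24,ITURI,NON_PRO_DS
it_non_25,ITURI,NON_PRO_DS
it_non_26,ITURI,NON_PRO_DS
it_non_27,ITURI,NON_PRO_DS
it_non_28,ITURI,NON_PRO_DS
it_non_29,ITURI,NON_PRO_DS
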