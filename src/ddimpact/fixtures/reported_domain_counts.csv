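domain,province,n_indicators,n_positive
SUPERVISION_MANAGEMENT,KONGO_CENTRAL,4,3
SUPERVISION_MANAGEMENT,ITURI,4,0
SERVICE_USE,KONGO_CENTRAL,14,9
SERVICE_USE,ITURI,13,12
NUTRITIONAL_HEALTH,KONGO_CENTRAL,9,5
NUTRITIONAL_HEALTH,ITURI,8,4
VACCINATION,KONGO_CENTRAL,7,7
VACCINATION,ITURI,7,5
REPRODUCTIVE_MATERNAL,KONGO_CENTRAL,19,9
REPRODUCTIVE_MATERNAL,ITURI,19,13
NEWBORN_CHILD,KONGO_CENTRAL,21,12
NEWBORN_CHILD,ITURI,14,12
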