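>tpr_unit_01
MEAWHMLANGYYKRGDYVVASFYYIKALELDPRT
>tpr_unit_02
AQPWYNLGPAYYKLGDYDEAIESYPNALELDPNS
>tpr_unit_03
NKAWYNVGNCYYKWDTYDRAIEYYQQALNLDPRS
>tpr_unit_04
AEAWYNLSNAYFKCEDYDEAINKYQKALELLPTH
>tpr_unit_05
ALAYYNLGGAYYKQGNYQLSLYYYAKALELDPRS
>tpr_unit_06
QEAWKRLGNQFKKQGDYDEGIEYYQMAPELDPRK
>tpr_unit_07
VEDYYLLGKAYYKQREVDAAFEAYPHALTLDPAG
>tpr_unit_08
AEKYYDLGEAFYLQSIYDEAIEHYQDALRLDPLV
>tpr_unit_09
ADAWFLMGPAYSLGGLYDAAIEYYQKALEIDSRK
>tpr_unit_10
AGAWPNLGNAFYIQGMYPLALCVYQVALALDPRY
>tpr_unit_11
LTDYGNLGNAYYAQIDYDEALEGYQCALALLPYS
>tpr_unit_12
SYPWYNLGNAYYKQGDYSAAGAHYQLALESDPRS
>tpr_unit_13
TVAWSFLGNAFTNQYLADDAISYYQNALELDSNN
>tpr_unit_14
AEAWQNVGNKYYKQGDYDQADHYYQKGIALDPRS
>tpr_unit_15
FEMWYQLGNAYYKQGDYDEAAEYWLKGSQFLPRS
>tpr_unit_16
GEAYYNLGNFYHTQYWYQSAIEYYQVALELNPRE
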