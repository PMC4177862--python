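subject_id,group,sex,age,site
cb01,CB,F,49,siteA
cb02,CB,M,41,siteA
cb03,CB,M,39,siteA
cb04,CB,M,58,siteA
cb05,CB,M,38,siteA
cb06,CB,F,31,siteA
cb07,CB,M,20,siteA
cb08,CB,M,23,siteA
cb09,CB,M,27,siteB
cb10,CB,F,27,siteB
cb11,CB,F,42,siteB
cb12,CB,M,60,siteB
cb13,CB,F,31,siteB
cb14,CB,F,23,siteB
cb15,CB,M,35,siteB
cb16,CB,M,57,siteB
cb17,CB,M,58,siteB
cb18,CB,F,19,siteB
cb19,CB,F,63,siteB
cb20,CB,F,26,siteC
cb21,CB,M,56,siteC
cb22,CB,F,21,siteC
cb23,CB,M,21,siteC
cb24,CB,F,41,siteC
cb25,CB,M,19,siteC
cb26,CB,M,23,siteC
cb27,CB,F,27,siteC
cb28,CB,M,23,siteC
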