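patient,myc_group,localizations
1,positive,cervical;thyroid
2,positive,mesenteric;paraaortic;iliac;pleural;subcutaneous
3,positive,fascia gerota;perirenal
4,positive,mediastinum;peritoneum
5,positive,lung;retroperitoneum;left kidney
6,positive,skeletal;spleen
7,positive,paraaortic;iliac;kidney;mons pubis
8,positive,cervical
9,positive,iliac;uterus
10,negative,central nervous system
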