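myc_group,ipet_status,eot_status,count
positive,negative,negative,43
positive,negative,positive,13
positive,negative,missing,1
positive,positive,negative,10
positive,positive,positive,13
positive,missing,negative,1
negative,negative,negative,89
negative,negative,positive,2
negative,negative,missing,5
negative,positive,negative,11
negative,positive,positive,16
negative,positive,missing,3
negative,missing,negative,2
negative,missing,positive,1
matched_negative,negative,negative,67
matched_negative,negative,positive,1
matched_negative,positive,negative,8
matched_negative,positive,positive,16
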