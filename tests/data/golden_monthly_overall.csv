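month,drugs,tests,group,category,numerator,denominator,percentage
2020-03,azathioprine+leflunomide+methotrexate,,,,5,10,50.0
2020-04,azathioprine+leflunomide+methotrexate,,,,5,10,50.0
2020-05,azathioprine+leflunomide+methotrexate,,,,5,10,50.0
2020-06,azathioprine+leflunomide+methotrexate,,,,5,10,50.0
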