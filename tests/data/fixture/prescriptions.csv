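patient_id,drug,issue_date
p0,methotrexate,2019-12-10
p0,methotrexate,2020-03-03
p0,methotrexate,2020-05-26
p0,methotrexate,2020-08-18
p0,methotrexate,2020-11-10
p1,methotrexate,2019-12-10
p1,methotrexate,2020-03-03
p1,methotrexate,2020-05-26
p1,methotrexate,2020-08-18
p1,methotrexate,2020-11-10
p2,azathioprine,2019-12-10
p2,azathioprine,2020-03-03
p2,azathioprine,2020-05-26
p2,azathioprine,2020-08-18
p2,azathioprine,2020-11-10
p3,azathioprine,2019-12-10
p3,azathioprine,2020-03-03
p3,azathioprine,2020-05-26
p3,azathioprine,2020-08-18
p3,azathioprine,2020-11-10
p4,leflunomide,2019-12-10
p4,leflunomide,2020-03-03
p4,leflunomide,2020-05-26
p4,leflunomide,2020-08-18
p4,leflunomide,2020-11-10
p5,leflunomide,2019-12-10
p5,leflunomide,2020-03-03
p5,leflunomide,2020-05-26
p5,leflunomide,2020-08-18
p5,leflunomide,2020-11-10
p6,methotrexate,2019-12-10
p6,methotrexate,2020-03-03
p6,methotrexate,2020-05-26
p6,methotrexate,2020-08-18
p6,methotrexate,2020-11-10
p7,methotrexate,2019-12-10
p7,methotrexate,2020-03-03
p7,methotrexate,2020-05-26
p7,methotrexate,2020-08-18
p7,methotrexate,2020-11-10
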