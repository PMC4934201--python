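# Retrieval window parameterizations for the O2-A and O2-B oxygen bands.
# set: candidate (parameter-comparison sets) or selected (operational choice).
# lambda_* in nm; degrees only for SFM (reflectance, fluorescence polynomial).
set,band,algorithm,label,lambda_in,lambda_left,lambda_right,degree_r,degree_f
candidate,O2A,FLD,O2A-FLD-c1,760.519,757.282,,,
candidate,O2A,FLD,O2A-FLD-c2,760.519,755.121,,,
candidate,O2A,FLD,O2A-FLD-c3,760.519,753.319,,,
candidate,O2A,3FLD,O2A-3FLD-c1,760.519,756.201,765.189,,
candidate,O2A,3FLD,O2A-3FLD-c2,760.519,751.877,769.135,,
candidate,O2A,3FLD,O2A-3FLD-c3,760.519,750.072,771.284,,
candidate,O2A,SFM,O2A-SFM-c1,760.519,756.201,771.284,1,1
candidate,O2A,SFM,O2A-SFM-c2,760.519,754.040,773.074,1,1
candidate,O2A,SFM,O2A-SFM-c3,760.519,752.237,775.220,1,1
candidate,O2B,FLD,O2B-FLD-c1,687.276,684.321,,,
candidate,O2B,FLD,O2B-FLD-c2,687.276,682.102,,,
candidate,O2B,FLD,O2B-FLD-c3,687.276,680.251,,,
candidate,O2B,3FLD,O2B-3FLD-c1,687.276,684.321,690.229,,
candidate,O2B,3FLD,O2B-3FLD-c2,687.276,682.442,692.441,,
candidate,O2B,3FLD,O2B-3FLD-c3,687.276,680.251,694.652,,
candidate,O2B,SFM,O2B-SFM-c1,687.276,685.060,690.229,2,1
candidate,O2B,SFM,O2B-SFM-c2,687.276,681.362,694.283,2,1
candidate,O2B,SFM,O2B-SFM-c3,687.276,679.141,696.124,2,1
selected,O2A,FLD,O2A-FLD-sel,760.519,759.081,,,
selected,O2A,3FLD,O2A-3FLD-sel,760.519,754.040,767.342,,
selected,O2A,SFM,O2A-SFM-sel,760.519,758.721,768.776,1,1
selected,O2B,FLD,O2B-FLD-sel,687.276,686.538,,,
selected,O2B,3FLD,O2B-3FLD-sel,687.276,686.538,688.015,,
selected,O2B,SFM,O2B-SFM-sel,687.276,683.581,691.704,2,1
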