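formulation_id,time_h,cumulative_pct
K-1 F-1,2,37.8
K-1 F-1,5,60.2
K-1 F-1,7,68.3
K-1 F-1,9,74.9
K-1 F-1,11,77.3
K-2 F-2,2,48.2
K-2 F-2,5,74.3
K-2 F-2,7,81.6
K-2 F-2,9,87.5
K-2 F-2,11,88.6
K-3 F-3,2,60.5
K-3 F-3,5,88.1
K-3 F-3,7,96.2
K-3 F-3,9,98.7
K-3 F-3,11,99.1
K-1 F-4,2,32.4
K-1 F-4,5,56.1
K-1 F-4,7,65.8
K-1 F-4,9,67.33
K-1 F-4,12,76.6
K-2 F-5,2,41.2
K-2 F-5,5,67.6
K-2 F-5,7,79.1
K-2 F-5,9,84.5
K-2 F-5,12,86.3
K-3 F-6,2,54.3
K-3 F-6,5,87.9
K-3 F-6,7,95.2
K-3 F-6,9,97.1
K-3 F-6,12,97.5
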