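formulation_id,time_h,cumulative_pct,source_note
K-1 F-1,2,37.8,lowest 2 h gastric-stage value; free ketoprofen; first tablet set (4% carbomer)
K-1 F-1,5,60.2,lowest value 5 h after start; first tablet set
K-1 F-1,7,68.3,lowest value 7 h after start; first tablet set
K-1 F-1,9,74.9,lowest value 9 h after start; first tablet set
K-1 F-1,11,77.3,lowest value at 11 h; first tablet set
K-2 F-2,2,48.2,intermediate 2 h gastric-stage value; 2:1 complex; first set
K-2 F-2,5,74.3,intermediate value at 5 h; first set
K-2 F-2,7,81.6,intermediate value at 7 h; first set
K-2 F-2,9,87.5,intermediate value at 9 h; first set
K-2 F-2,11,88.6,intermediate value at 11 h; first set
K-3 F-3,2,60.5,highest 2 h gastric-stage value; 1:1 complex; first set
K-3 F-3,5,88.1,maximum value at 5 h; first set
K-3 F-3,7,96.2,maximum value at 7 h; first set
K-3 F-3,9,98.7,maximum value at 9 h; first set
K-3 F-3,11,99.1,maximum value at 11 h; first set
K-1 F-4,2,32.4,2 h gastric-stage value; free ketoprofen; second set (8% carbomer)
K-1 F-4,5,56.1,reported at 5 h; source text mislabels this formulation as K-1 F-1 (context implies K-1 F-4)
K-1 F-4,7,65.8,reported at 7 h; source text mislabels this formulation as K-1 F-1 (context implies K-1 F-4)
K-1 F-4,9,67.33,reported at 9 h (two decimals as printed); mislabelled K-1 F-1 in source text
K-1 F-4,12,76.6,reported at 12 h; mislabelled K-1 F-1 in source text
K-2 F-5,2,41.2,2 h gastric-stage value; 2:1 complex; second set
K-2 F-5,5,67.6,reported at 5 h; second set
K-2 F-5,7,79.1,reported at 7 h; second set
K-2 F-5,9,84.5,reported at 9 h; second set
K-2 F-5,12,86.3,reported at 12 h; second set
K-3 F-6,2,54.3,2 h gastric-stage value; 1:1 complex; second set
K-3 F-6,5,87.9,reported at 5 h; second set
K-3 F-6,7,95.2,reported at 7 h; second set
K-3 F-6,9,97.1,reported at 9 h; maximum reached and held to 12 h
K-3 F-6,12,97.5,reported at 12 h; second set
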