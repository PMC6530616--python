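# Example survey of maximum organ doses from normal-pitch MVCT delivery
# on a helical tomotherapy unit, across five treatment sites (21 organs).
# total_max_cGy and percent are the reported (display-rounded) survey values;
# totals were accumulated from unrounded per-fraction maxima, so they are not
# exactly max_per_fx_cGy * n_fractions for every row.
region,organ,fraction_dose_cGy,n_fractions,max_per_fx_cGy,total_max_cGy,percent
brain,Brain,300,10,1.88,18.80,0.63
brain,Brain stem,300,10,1.66,16.57,0.55
brain,R-eye,300,10,1.77,17.67,0.59
brain,L-eye,300,10,1.84,18.40,0.61
head_and_neck,L-parotid,180,39,1.62,63.14,0.90
head_and_neck,R-parotid,180,39,1.92,74.72,1.06
head_and_neck,Oral cavity,180,39,1.86,72.35,1.03
head_and_neck,Spinal cord,180,39,1.73,67.51,0.96
lung,L-lung,180,33,1.68,55.34,0.93
lung,R-lung,180,33,1.55,51.18,0.86
lung,Spinal cord,180,33,1.51,49.96,0.84
lung,Heart,180,33,1.63,53.79,0.91
abdomen,Stomach,180,28,1.70,47.60,0.94
abdomen,R-kidney,180,28,1.65,46.20,0.92
abdomen,L-kidney,180,28,1.59,44.38,0.88
abdomen,Spinal cord,180,28,1.53,42.92,0.85
abdomen,Duodenum,180,28,1.60,44.88,0.89
prostate,Bladder,200,38,1.24,47.27,0.62
prostate,FHs,200,38,1.53,58.22,0.77
prostate,Rectum,200,38,1.44,54.68,0.72
prostate,Prostate,200,38,1.31,49.82,0.66
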