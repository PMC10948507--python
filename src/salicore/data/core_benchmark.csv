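# Published representativeness benchmark for a 64-of-318 Miscanthus mini-core:
# per-trait coincidence rate of range (CR%), variable rate (VR%), variance
# difference (VD%), mean difference (MD%), and Shannon-Weaver indices for the
# core and entire collections.
trait,cr_pct,vr_pct,vd_pct,md_pct,h_core,h_entire
RGR,99.97,175.87,43.14,8.69,3.97,5.63
RNIL,91.18,128.54,22.20,3.57,4.09,5.70
RLER,94.08,137.70,27.38,2.38,4.10,5.72
SWC,92.25,132.98,24.80,4.48,4.10,5.72
RWC,79.34,101.32,1.30,5.60,4.10,5.71
Sen,100.00,131.25,23.81,0.18,4.14,5.75
SNC,100.00,142.09,29.62,0.30,4.13,5.74
RNC,79.75,121.40,17.63,0.45,4.13,5.73
SN/RN,99.58,157.12,36.35,0.64,4.11,5.73
SKC,94.49,145.92,31.47,1.86,4.15,5.76
RKC,94.93,137.77,27.41,0.56,4.13,5.74
SK/RK,96.39,146.88,31.92,3.29,4.11,5.73
SK/N,97.92,172.77,42.12,4.64,4.11,5.73
RK/N,100.00,144.69,30.89,0.77,4.10,5.72
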