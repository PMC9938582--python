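# Best-effort reconstruction of a 39-peak total-serum N-glycome annotation.
# Structure labels use the Oxford notation (A = antennae, F leading = core
# fucose, F after antenna count = antennary fucose, B = bisecting GlcNAc,
# G = galactoses, S = sialic acids, M = oligomannose).  Overridable.
peak_id	structure_label
GP1	A1
GP2	FA1
GP3	A2
GP4	A2B
GP5	FA2
GP6	FA2[6]BG1
GP7	FA2[3]BG1
GP8	A2G2
GP9	A2[6]G1
GP10	FA2[6]G1
GP11	FA2[3]G1
GP12	FA2BG1
GP13	M5
GP14	FA2G2
GP15	FA2BG2
GP16	M6
GP17	A2G2S1
GP18	FA2G2S1
GP19	FA2BG2S1
GP20	M7
GP21	A2G2S2
GP22	FA2G2S2
GP23	FA2BG2S2
GP24	M8
GP25	A3G3S1
GP26	A3G3S2
GP27	A3F1G3S2/A3G3S3
GP28	M9
GP29	A3G3S3
GP30	A3F1G3S3
GP31	A4G4S2
GP32	A4G4S3
GP33	A2BG2
GP34	A4F1G4S2
GP35	A4BG4S3
GP36	A4F1G4S3
GP37	A4G4S4
GP38	A3BG3S3
GP39	A4F1G4S4/A4F2G4S4
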