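# Default derived-trait definitions: 16 summaries of structurally related
# peaks, a best-effort reconstruction of standard total-serum glycome traits
# (low/high branching, core/antennary fucosylation, bisection, oligomannose,
# galactosylation and sialylation degrees).  Trait value = sum(numerator
# peaks) / sum(denominator peaks); denominator "all" means all 39 peaks.
# Fully overridable: analyses always use the spec actually supplied.
- name: LB   # low-branched mono- and biantennary N-glycans
  numerator: [GP1, GP2, GP3, GP4, GP5, GP6, GP7, GP8, GP9, GP10, GP11, GP12,
              GP14, GP15, GP17, GP18, GP19, GP21, GP22, GP23, GP33]
  denominator: all
- name: HB   # high-branched tri- and tetraantennary N-glycans
  numerator: [GP25, GP26, GP27, GP29, GP30, GP31, GP32, GP34, GP35, GP36,
              GP37, GP38, GP39]
  denominator: all
- name: HM   # oligomannose
  numerator: [GP13, GP16, GP20, GP24, GP28]
  denominator: all
- name: CF   # core fucosylation (alpha1,6 to the reducing-end GlcNAc)
  numerator: [GP2, GP5, GP6, GP7, GP10, GP11, GP12, GP14, GP15, GP18, GP19,
              GP22, GP23]
  denominator: all
- name: AF   # antennary fucosylation (alpha1,3 to antenna GlcNAc)
  numerator: [GP27, GP30, GP34, GP36, GP39]
  denominator: all
- name: BIS  # bisecting GlcNAc
  numerator: [GP4, GP6, GP7, GP12, GP15, GP19, GP23, GP33, GP35, GP38]
  denominator: all
- name: G0   # agalactosylated complex glycans
  numerator: [GP1, GP2, GP3, GP4, GP5]
  denominator: all
- name: G1   # monogalactosylated
  numerator: [GP6, GP7, GP9, GP10, GP11, GP12]
  denominator: all
- name: G2   # digalactosylated
  numerator: [GP8, GP14, GP15, GP17, GP18, GP19, GP21, GP22, GP23, GP33]
  denominator: all
- name: G3   # trigalactosylated
  numerator: [GP25, GP26, GP27, GP29, GP30, GP38]
  denominator: all
- name: G4   # tetragalactosylated
  numerator: [GP31, GP32, GP34, GP35, GP36, GP37, GP39]
  denominator: all
- name: S0   # neutral (asialylated) complex glycans
  numerator: [GP1, GP2, GP3, GP4, GP5, GP6, GP7, GP8, GP9, GP10, GP11, GP12,
              GP14, GP15, GP33]
  denominator: all
- name: S1   # monosialylated
  numerator: [GP17, GP18, GP19, GP25]
  denominator: all
- name: S2   # disialylated
  numerator: [GP21, GP22, GP23, GP26, GP27, GP31, GP34]
  denominator: all
- name: S3   # trisialylated
  numerator: [GP29, GP30, GP32, GP35, GP36, GP38]
  denominator: all
- name: S4   # tetrasialylated
  numerator: [GP37, GP39]
  denominator: all
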