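# Demo chemical parameter sets: phenols, parabens and phthalates commonly
# measured in urinary biomonitoring, with their health-based guidance values
# (TDI/ADI from EFSA/SCCS-type evaluations, RfD from US EPA IRIS).
#
# The ADME entries (fub, clint, ka, Vmax/Km) are literature-plausible demo
# values assembled for illustration and testing; substitute measured values
# for any real assessment.  Units are embedded in the field names/schema:
#   mw g/mol; clint µL/min/10^6 hepatocytes; ka 1/h; vmax_invitro µmol/h/mg
#   microsomal protein; km_um µM; tdi/rfd/group_tdi mg/kg/day.
chemicals:
  BPA:
    cas: "80-05-7"
    mw: 228.29
    log_kow: 3.32
    water_solubility_mgl: 120.0
    fub: 0.05
    clint: 30.0
    ka: 2.0
    tdi: 0.004
    rfd: 0.05
    metabolic_steps:
      - product:
          name: BPA-glucuronide
          cas: "267244-08-6"
          mw: 404.41
          log_kow: 0.4
          fub: 0.6
          ka: 0.0
        vmax_invitro: 1.6
        km_um: 50.0
  TCS:
    cas: "3380-34-5"
    mw: 289.54
    log_kow: 4.76
    water_solubility_mgl: 10.0
    fub: 0.005
    clint: 70.0
    ka: 1.5
    tdi: 0.047
    rfd: 0.3
    metabolic_steps:
      - product:
          name: TCS-glucuronide
          mw: 465.68
          log_kow: 1.1
          fub: 0.4
          ka: 0.0
        vmax_invitro: 0.9
        km_um: 30.0
  BP-3:
    cas: "131-57-7"
    mw: 228.24
    log_kow: 3.79
    fub: 0.03
    clint: 25.0
    ka: 1.8
    tdi: 0.1
  MeP:
    cas: "99-76-3"
    mw: 152.15
    log_kow: 1.96
    fub: 0.40
    clint: 90.0
    ka: 2.5
    group_tdi_id: parabens_MeP_EtP
    group_tdi: 10.0
  EtP:
    cas: "120-47-8"
    mw: 166.17
    log_kow: 2.47
    fub: 0.35
    clint: 80.0
    ka: 2.3
    group_tdi_id: parabens_MeP_EtP
    group_tdi: 10.0
  n-PrP:
    cas: "94-13-3"
    mw: 180.20
    log_kow: 3.04
    fub: 0.30
    clint: 60.0
    ka: 2.1
    tdi: 0.02
  n-BuP:
    cas: "94-26-8"
    mw: 194.23
    log_kow: 3.57
    fub: 0.20
    clint: 50.0
    ka: 2.0
    tdi: 0.02
  DnBP:
    cas: "84-74-2"
    mw: 278.34
    log_kow: 4.50
    fub: 0.02
    clint: 40.0
    ka: 1.2
    tdi: 0.01
    rfd: 0.1
    metabolic_steps:
      - product:
          name: MnBP
          cas: "131-70-4"
          mw: 222.24
          log_kow: 2.84
          fub: 0.1
          ka: 0.0
        vmax_invitro: 2.0
        km_um: 60.0
  BBzP:
    cas: "85-68-7"
    mw: 312.36
    log_kow: 4.73
    fub: 0.015
    clint: 45.0
    ka: 1.0
    tdi: 0.5
    rfd: 0.2
    metabolic_steps:
      - product:
          name: MBzP
          cas: "2528-16-7"
          mw: 256.25
          log_kow: 3.0
          fub: 0.08
          ka: 0.0
        vmax_invitro: 1.8
        km_um: 70.0
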