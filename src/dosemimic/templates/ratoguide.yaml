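# Dose-mimicking objective template (21 rows).
# Upper objectives bound every voxel of the structure from above (volume 0),
# Lower objectives from below (volume 100).  Doses in Gy for a 60 Gy / 30 fx
# prescription; priorities are linear penalty weights.
name: ratoguide
objectives:
  - {structure: CTV,                  kind: Upper, volume: 0,   dose: 59.4, priority: 800}
  - {structure: CTV,                  kind: Lower, volume: 100, dose: 60.6, priority: 950}
  - {structure: PTV,                  kind: Upper, volume: 0,   dose: 59.4, priority: 800}
  - {structure: PTV,                  kind: Lower, volume: 100, dose: 59.4, priority: 950}
  - {structure: PTV-CTV,              kind: Upper, volume: 0,   dose: 59.4, priority: 800}
  - {structure: PTV-CTV,              kind: Lower, volume: 100, dose: 59.4, priority: 950}
  - {structure: "PTV-Dose99.0-110.0%", kind: Lower, volume: 100, dose: 59.4, priority: 950}
  - {structure: "dose_5.0-8.3%",      kind: Upper, volume: 0,   dose: 5,    priority: 500}
  - {structure: "dose_8.3-33.0%",     kind: Upper, volume: 0,   dose: 20,   priority: 500}
  - {structure: "dose_33.0-40.0%",    kind: Upper, volume: 0,   dose: 22.2, priority: 550}
  - {structure: "dose_40.0-60.0%",    kind: Upper, volume: 0,   dose: 34.2, priority: 600}
  - {structure: "dose_60.0-80.0%",    kind: Upper, volume: 0,   dose: 46.2, priority: 700}
  - {structure: "dose_70.0-90.0%",    kind: Upper, volume: 0,   dose: 52.2, priority: 800}
  - {structure: "dose_80.0-95.0%",    kind: Upper, volume: 0,   dose: 58.8, priority: 800}
  - {structure: "dose_103.0-110.0%",  kind: Upper, volume: 0,   dose: 61.2, priority: 700}
  - {structure: Esophagus,            kind: Upper, volume: 0,   dose: 60,   priority: 800}
  - {structure: Heart,                kind: Upper, volume: 0,   dose: 60,   priority: 800}
  - {structure: "Lungs/Dose5.0-8.3%", kind: Upper, volume: 0,   dose: 3,    priority: 950}
  - {structure: "Lungs/Dose8.3-33.0%", kind: Upper, volume: 0,  dose: 16.2, priority: 800}
  - {structure: SpinalCord,           kind: Upper, volume: 0,   dose: 35,   priority: 800}
  - {structure: SpinalCord_PRV,       kind: Upper, volume: 0,   dose: 38,   priority: 800}
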