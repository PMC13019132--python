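# DVH-prediction objective template: only the fixed target and spinal-cord
# rows are instantiable objectives.  OAR "line" objectives and the
# normal-tissue objective are model-generated at planning time by the
# commercial system; they are carried here as metadata and never turned
# into DoseObjective rows.  The cord rows print no priority in the source
# template ("generated"); 100 is used as the documented default.
name: rapidplan_static
objectives:
  - {structure: CTV,            kind: Upper, volume: 0,   dose: 59.4, priority: 80}
  - {structure: CTV,            kind: Lower, volume: 100, dose: 60.6, priority: 100}
  - {structure: PTV,            kind: Upper, volume: 0,   dose: 59.4, priority: 80}
  - {structure: PTV,            kind: Lower, volume: 100, dose: 59.4, priority: 100}
  - {structure: PTV-CTV,        kind: Upper, volume: 0,   dose: 59.4, priority: 80}
  - {structure: PTV-CTV,        kind: Lower, volume: 100, dose: 59.4, priority: 100}
  - {structure: SpinalCord,     kind: Upper, volume: 0,   dose: 35,   priority: 100}
  - {structure: SpinalCord_PRV, kind: Upper, volume: 0,   dose: 38,   priority: 100}
line_objectives:
  - {structure: Lungs,     volume: generated, dose: generated, priority: generated}
  - {structure: Esophagus, volume: generated, dose: generated, priority: generated}
  - {structure: Heart,     volume: generated, dose: generated, priority: generated}
normal_tissue_objective:
  distance_from_target_cm: 0.5
  start_dose_percent: 100
  end_dose_percent: 40
  falloff_cm: 0.25
  priority: 100
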