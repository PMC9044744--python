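# Canonical column registry for directly-compressed ODT formulation tables.
# Categories: id, api, composition, manufacturing, descriptor, target.
# Composition values are mass percentages (topological encoding: absent = 0).
id:
  - "Record ID"
api:
  - "API name"
composition:
  - "API [%]"
  - "Mannitol [%]"
  - "MCC [%]"
  - "Lactose [%]"
  - "SSG [%]"
  - "CC-Na [%]"
  - "Crospovidone [%]"
  - "L-HPC [%]"
  - "Pregelatinized starch [%]"
  - "Sodium carboxymethyl starch [%]"
  - "2-HP-beta-CD [%]"
  - "beta-CD [%]"
  - "CD-methacrylate [%]"
  - "Amberlite [%]"
  - "Eudragit EPO [%]"
  - "Poloxamer [%]"
  - "PVP [%]"
  - "SLS [%]"
  - "PVA [%]"
  - "Camphor [%]"
  - "MgSt [%]"
  - "Aerosil [%]"
  - "Colloidal silica [%]"
  - "Talc [%]"
  - "SSF [%]"
  - "HPMC [%]"
  - "Calcium silicate [%]"
  - "Sodium bicarbonate [%]"
manufacturing:
  - "Tablet mass [mg]"
  - "Thickness [mm]"
  - "Punch die of tablet press [mm]"
  - "Hardness [N]"
  - "Lateral tablet surface area [mm2]"
  - "Flat tablet surface area [mm2]"
  - "Total tablet surface area [mm2]"
  - "Volume (tablet) [mm3]"
  - "Surface area to volume ratio [mm]"
target:
  - "Disintegration time [s]"
# Observed min/max of manufacturing parameters and target in the curated
# directly-compressed ODT database; used as the default validation envelope.
envelope:
  "Tablet mass [mg]": [67.13, 1179.98]
  "Thickness [mm]": [1.86, 6.5]
  "Punch die of tablet press [mm]": [5.5, 16.0]
  "Hardness [N]": [2.4, 155.43]
  "Disintegration time [s]": [4.98, 140.0]
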