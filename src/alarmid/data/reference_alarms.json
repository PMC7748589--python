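[
  {"name": "Aisys CS2 Ventilator - Critical", "frequencies_hz": [398, 1195, 2003], "period_s": 0.49, "peak_width_s": 0.06},
  {"name": "Aisys CS2 Ventilator - Warning", "frequencies_hz": [398, 1195, 2003], "period_s": 0.366, "peak_width_s": 0.178},
  {"name": "Alaris PC 8015 IV Pump", "frequencies_hz": [2196], "period_s": 2.06},
  {"name": "BD Pyxis Medication Station", "frequencies_hz": [883], "period_s": 1.1},
  {"name": "Braun Outlook 400 IV Pump - Alarm", "frequencies_hz": [528, 1572, 2616], "period_s": 3.68},
  {"name": "Braun Outlook 400 IV Pump - Starting", "frequencies_hz": [786, 2347], "period_s": 1.05, "peak_width_s": 0.1},
  {"name": "Flowtron SCD Pump", "frequencies_hz": [2713], "period_s": 0.46, "peak_width_s": 0.1},
  {"name": "GE Carescape B650 Monitor - Warning", "frequencies_hz": [441, 1187], "period_s": 2.75},
  {"name": "GE Carescape B650 Monitor - Critical", "frequencies_hz": [506, 1497], "period_s": 1.02},
  {"name": "Megadyne Electrosurgical Unit", "frequencies_hz": [2315], "period_s": 0.64},
  {"name": "Omnicell (Supply Cabinet) - Door Open", "frequencies_hz": [2024, 2261], "period_s": 1.0},
  {"name": "Omnicell Medication Dispensing System", "frequencies_hz": [700, 1400, 1766], "period_s": 0.325, "peak_width_s": 0.15},
  {"name": "Philips Intellivue MP30 Monitor - Warning", "frequencies_hz": [485], "period_s": 2.104, "peak_width_s": 0.24},
  {"name": "Philips Intellivue MP30 Monitor - Medium", "frequencies_hz": [485, 2401], "period_s": 2.091, "peak_width_s": 0.5}
]
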