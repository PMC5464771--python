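{
  "_comment": "Named synthetic-data fixtures. 'source' records provenance of each anchoring value: 'figure' = printed mean +/- SEM in the study figures/tables, 'reported' = cited constant, 'invented-ordering-only' = value chosen here, only the ordering across conditions is anchored.",
  "tracks": {
    "icam-0.5kPa": {
      "migrating_speed_mean": 12.4,
      "migrating_speed_sd": 3.0,
      "frac_arrested": 0.0,
      "source": "figure",
      "note": "ICAM-1-only coating, 0.5 kPa gel; mean +/- SEM 12.4 +/- 0.3 um/min at n 50-100; sd set to 3.0 so cohort SEM ~ 0.3 at n=100"
    },
    "icam-6.4kPa": {
      "migrating_speed_mean": 13.1,
      "migrating_speed_sd": 3.0,
      "frac_arrested": 0.0,
      "source": "figure",
      "note": "ICAM-1-only coating, 6.4 kPa gel; 13.1 +/- 0.3 um/min"
    },
    "icam-100kPa": {
      "migrating_speed_mean": 15.5,
      "migrating_speed_sd": 4.0,
      "frac_arrested": 0.0,
      "source": "figure",
      "note": "ICAM-1-only coating, 100 kPa gel; 15.5 +/- 0.4 um/min; sd set to 4.0 so cohort SEM ~ 0.4 at n=100"
    },
    "acd3-0.5kPa": {
      "migrating_speed_mean": 12.4,
      "migrating_speed_sd": 3.0,
      "frac_arrested": 0.2,
      "source": "invented-ordering-only",
      "note": "aCD3+aCD28+ICAM-1 coating; arrest fractions are figure-encoded, only the ordering soft < mid < stiff < glass is anchored"
    },
    "acd3-6.4kPa": {
      "migrating_speed_mean": 13.1,
      "migrating_speed_sd": 3.0,
      "frac_arrested": 0.3,
      "source": "invented-ordering-only"
    },
    "acd3-100kPa": {
      "migrating_speed_mean": 13.5,
      "migrating_speed_sd": 4.0,
      "frac_arrested": 0.5,
      "source": "invented-ordering-only",
      "note": "non-arrested cells decelerate on the stiff gel under TCR triggering; mean lowered accordingly (value not printed)"
    },
    "acd3-glass": {
      "migrating_speed_mean": 12.0,
      "migrating_speed_sd": 4.0,
      "frac_arrested": 0.8,
      "source": "invented-ordering-only"
    }
  },
  "indentation": {
    "hela-1.5kPa": {
      "E_true_pa": 1430.0,
      "source": "figure",
      "note": "HeLa cells on 1.5 kPa PDMS: 1.43 +/- 0.15 kPa, n=13"
    },
    "hela-28kPa": {
      "E_true_pa": 1720.0,
      "source": "figure",
      "note": "HeLa cells on 28 kPa PDMS: 1.72 +/- 0.2 kPa, n=15"
    }
  },
  "rheology": {
    "pa-5pct-sweep": {
      "G_plateau_true_pa": 2212.0,
      "noise_sd_pa": 20.0,
      "source": "figure",
      "note": "5% acrylamide / 0.5% bis gel: G' = 2212 +/- 79 Pa over n=15 samples"
    }
  },
  "gels": {
    "pa-0.5kPa": {
      "acrylamide_pct": 3.0,
      "bis_pct": 0.25,
      "young_modulus_pa": 513.0,
      "young_modulus_sem_pa": 48.0,
      "basis": "measured",
      "source": "figure"
    },
    "pa-6.4kPa": {
      "acrylamide_pct": 5.0,
      "bis_pct": 0.5,
      "young_modulus_pa": 6416.0,
      "young_modulus_sem_pa": 228.0,
      "g_prime_pa": 2212.0,
      "g_prime_sem_pa": 79.0,
      "basis": "measured",
      "source": "figure"
    },
    "pa-100kPa": {
      "acrylamide_pct": 18.0,
      "bis_pct": 0.38,
      "young_modulus_pa": 100000.0,
      "basis": "reported",
      "source": "reported",
      "note": "cited literature constant for this formulation, not computed from a sweep"
    }
  }
}
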