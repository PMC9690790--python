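{
 "name": "stabilization_effect",
 "weight": 1.0,
 "note": "Criterion and sub-criterion weights are the published panel values; indicator-level local weights are back-computed as printed comprehensive weight over its sibling-group sum (the published table prints only comprehensive weights at the indicator level, summing to 1.003 due to rounding).",
 "children": [
  {
   "name": "soil",
   "weight": 0.544,
   "children": [
    {
     "name": "soil_fertility",
     "weight": 0.295,
     "children": [
      {
       "name": "pH",
       "weight": 0.3354838709677419,
       "printed_comprehensive": 0.052
      },
      {
       "name": "SOM",
       "weight": 0.13548387096774195,
       "printed_comprehensive": 0.021
      },
      {
       "name": "CEC",
       "weight": 0.10967741935483871,
       "printed_comprehensive": 0.017
      },
      {
       "name": "A-N",
       "weight": 0.13548387096774195,
       "printed_comprehensive": 0.021
      },
      {
       "name": "A-P",
       "weight": 0.14193548387096774,
       "printed_comprehensive": 0.022
      },
      {
       "name": "A-K",
       "weight": 0.14193548387096774,
       "printed_comprehensive": 0.022
      }
     ]
    },
    {
     "name": "soil_heavy_metal",
     "weight": 0.705,
     "children": [
      {
       "name": "AHM",
       "weight": 0.7672634271099744,
       "printed_comprehensive": 0.3
      },
      {
       "name": "THM",
       "weight": 0.23273657289002556,
       "printed_comprehensive": 0.091
      }
     ]
    }
   ]
  },
  {
   "name": "crop",
   "weight": 0.316,
   "children": [
    {
     "name": "crop_growth",
     "weight": 0.265,
     "children": [
      {
       "name": "biomass",
       "weight": 0.2941176470588236,
       "printed_comprehensive": 0.025
      },
      {
       "name": "production",
       "weight": 0.7058823529411765,
       "printed_comprehensive": 0.06
      }
     ]
    },
    {
     "name": "pollution_accumulation",
     "weight": 0.735,
     "children": [
      {
       "name": "hm_edible",
       "weight": 0.646551724137931,
       "printed_comprehensive": 0.15
      },
      {
       "name": "hm_above_ground",
       "weight": 0.1206896551724138,
       "printed_comprehensive": 0.028
      },
      {
       "name": "hm_roots",
       "weight": 0.2327586206896552,
       "printed_comprehensive": 0.054
      }
     ]
    }
   ]
  },
  {
   "name": "amendment",
   "weight": 0.14,
   "children": [
    {
     "name": "cost",
     "weight": 0.30000000000000004,
     "printed_comprehensive": 0.042
    },
    {
     "name": "hm_amendment",
     "weight": 0.32142857142857145,
     "printed_comprehensive": 0.045
    },
    {
     "name": "stability",
     "weight": 0.3785714285714286,
     "printed_comprehensive": 0.053
    }
   ]
  }
 ]
}
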