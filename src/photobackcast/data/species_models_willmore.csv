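species,scale_m,term,beta,se,t,p
Canada Jay,1250,Intercept,-4.41,0.83,-5.29,7.2e-06
Canada Jay,1250,coniferous forest,0.04,0.01,4.23,1.7e-04
Canada Jay,1250,shrubs,0.06,0.03,2.54,0.02
Wilson's Warbler,1250,Intercept,-2.04,0.37,-5.51,3.8e-06
Wilson's Warbler,1250,herbaceous,-0.06,0.03,-1.82,0.08
Wilson's Warbler,1250,shrubs,0.08,0.02,3.37,1.9e-03
Savannah Sparrow,4250,Intercept,-5.26,0.81,-6.50,7.9e-11
Savannah Sparrow,4250,herbaceous,0.24,0.07,3.53,4.2e-04
Golden-crowned Kinglet,250,Intercept,-6.22,1.39,-4.46,8.1e-06
Golden-crowned Kinglet,250,coniferous forest,0.05,0.01,3.38,7.2e-04
Golden-crowned Kinglet,250,wetland,0.05,0.01,3.31,9.3e-04
Golden-crowned Kinglet,250,shrubs,0.04,0.02,2.13,0.03
Ruby-crowned Kinglet,1500,Intercept,-4.85,1.22,-3.97,3.7e-04
Ruby-crowned Kinglet,1500,coniferous forest,0.03,0.01,2.34,0.03
Ruby-crowned Kinglet,1500,broadleaf forest,0.73,0.36,2.03,0.05
Ruby-crowned Kinglet,1500,wetland,0.04,0.02,1.93,0.06
Ruby-crowned Kinglet,1500,shrubs,0.05,0.03,1.81,0.08
Dark-eyed Junco,1250,Intercept,-1.56,0.27,-5.75,1.7e-06
Dark-eyed Junco,1250,herbaceous,-0.14,0.05,-3.11,3.7e-03
Dark-eyed Junco,1250,shrubs,0.04,0.02,2.50,0.02
American Robin,1500,Intercept,-0.80,0.37,-2.16,0.04
American Robin,1500,coniferous forest,-0.03,0.01,-2.98,0.01
American Robin,1500,broadleaf forest,0.49,0.26,1.90,0.07
Hermit Thrush,500,Intercept,-2.36,0.53,-4.45,8.7e-05
Hermit Thrush,500,coniferous forest,0.01,0.01,2.00,0.05
Hermit Thrush,500,broadleaf forest,0.94,0.33,2.84,0.01
Hermit Thrush,500,wetland,-0.02,0.02,-0.95,0.35
Pine Siskin,4500,Intercept,-1.02,0.40,-2.59,0.01
Pine Siskin,4500,coniferous forest,0.02,0.01,2.19,0.03
Pine Siskin,4500,broadleaf forest,-2.13,0.66,-3.25,2.6e-03
American Pipit,250,Intercept,0.21,0.20,1.09,0.28
American Pipit,250,coniferous forest,-0.08,0.02,-5.26,7.9e-06
American Pipit,250,wetland,-0.03,0.01,-2.57,0.01
American Pipit,250,broadleaf forest,0.73,0.23,3.13,3.5e-03
Golden-crowned Sparrow,250,Intercept,-0.11,0.22,-0.52,0.60
Golden-crowned Sparrow,250,coniferous forest,-0.08,0.02,-4.24,1.6e-04
Golden-crowned Sparrow,250,wetland,-0.03,0.01,-2.04,0.05
Golden-crowned Sparrow,250,broadleaf forest,1.28,0.38,3.34,2.1e-03
Swainson's Thrush,4000,Intercept,-9.52,2.00,-4.77,3.6e-05
Swainson's Thrush,4000,coniferous forest,0.07,0.02,3.87,4.8e-04
Swainson's Thrush,4000,wetland,0.11,0.04,2.97,0.01
Swainson's Thrush,4000,shrubs,0.14,0.05,2.92,0.01
Swainson's Thrush,4000,broadleaf forest,1.47,0.66,2.22,0.03
Yellow-rumped Warbler,4500,Intercept,-1.01,0.93,-1.09,0.29
Yellow-rumped Warbler,4500,coniferous forest,0.03,0.01,2.52,0.02
Yellow-rumped Warbler,4500,herbaceous,-0.13,0.06,-1.98,0.06
Chipping Sparrow,250,Intercept,1.05,0.47,2.24,0.03
Chipping Sparrow,250,coniferous forest,-0.02,0.01,-2.97,0.01
Chipping Sparrow,250,wetland,-0.02,0.01,-2.81,0.01
Chipping Sparrow,250,herbaceous,-0.01,0.01,-1.61,0.12
Varied Thrush,3750,Intercept,-3.79,0.89,-4.25,1.6e-04
Varied Thrush,3750,broadleaf forest,1.94,0.66,2.95,0.01
Varied Thrush,3750,wetland,-0.11,0.10,-1.12,0.27
Varied Thrush,3750,shrubs,0.05,0.04,1.25,0.22
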