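vintage,region,price_category,index,detail_flag
2010,London,food_nonalcoholic,101.9,detailed
2010,London,alcohol_tobacco,102.6,detailed
2010,London,restaurants_hotels,111.5,detailed
2010,Scotland,food_nonalcoholic,99.9,detailed
2010,Scotland,alcohol_tobacco,99.6,detailed
2010,Scotland,restaurants_hotels,100.2,detailed
2010,Wales,food_nonalcoholic,100.6,detailed
2010,Wales,alcohol_tobacco,102.0,detailed
2010,Wales,restaurants_hotels,95.6,detailed
2010,Northern Ireland,food_nonalcoholic,99.8,detailed
2010,Northern Ireland,alcohol_tobacco,98.9,detailed
2010,Northern Ireland,restaurants_hotels,98.6,detailed
2010,South East,food_nonalcoholic,101.3,aggregate
2010,South East,alcohol_tobacco,101.3,aggregate
2010,South East,restaurants_hotels,101.3,aggregate
2010,Eastern,food_nonalcoholic,99.9,aggregate
2010,Eastern,alcohol_tobacco,99.9,aggregate
2010,Eastern,restaurants_hotels,99.9,aggregate
2010,West Midlands,food_nonalcoholic,98.7,aggregate
2010,West Midlands,alcohol_tobacco,98.7,aggregate
2010,West Midlands,restaurants_hotels,98.7,aggregate
2010,South West,food_nonalcoholic,102.1,aggregate
2010,South West,alcohol_tobacco,102.1,aggregate
2010,South West,restaurants_hotels,102.1,aggregate
2010,East Midlands,food_nonalcoholic,99.7,aggregate
2010,East Midlands,alcohol_tobacco,99.7,aggregate
2010,East Midlands,restaurants_hotels,99.7,aggregate
2010,North West,food_nonalcoholic,99.0,aggregate
2010,North West,alcohol_tobacco,99.0,aggregate
2010,North West,restaurants_hotels,99.0,aggregate
2010,North East,food_nonalcoholic,98.9,aggregate
2010,North East,alcohol_tobacco,98.9,aggregate
2010,North East,restaurants_hotels,98.9,aggregate
2010,Yorkshire,food_nonalcoholic,97.9,aggregate
2010,Yorkshire,alcohol_tobacco,97.9,aggregate
2010,Yorkshire,restaurants_hotels,97.9,aggregate
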