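# Published five-year BIA results, scenario 2: abemaciclib + ribociclib taken up
# equally, rising 30% -> 80% of the market, displacing palbociclib/other standard care.
# Same layout as scenario1_results.csv; monetary cells in integer QAR as printed.
scenario_id,year,n,baseline_total,arm_id,arm_label,arm_role,share,arm_cost,scenario_total,incremental,per_patient,source
s2,2024,173,27102920,plbo_other,PLBO/Other Tx,comparator_mix,0.70,18972044,27893201,790281,4568,scenario-2 results table year 1
s2,2024,173,27102920,abma_ribo,ABMA & RIBO,intervention,0.30,8921157,27893201,790281,4568,scenario-2 results table year 1
s2,2025,182,28458066,plbo_other,PLBO/Other Tx,comparator_mix,0.60,17074840,29564460,1106393,6079,scenario-2 results table year 2
s2,2025,182,28458066,abma_ribo,ABMA & RIBO,intervention,0.40,12489620,29564460,1106393,6079,scenario-2 results table year 2
s2,2026,191,29922877,plbo_other,PLBO/Other Tx,comparator_mix,0.50,14961439,31377055,1454178,7613,scenario-2 results table year 3
s2,2026,191,29922877,abma_ribo,ABMA & RIBO,intervention,0.50,16415617,31377055,1454178,7613,scenario-2 results table year 3
s2,2027,201,31419021,plbo_other,PLBO/Other Tx,comparator_mix,0.35,10996657,33403974,1984953,9875,scenario-2 results table year 4
s2,2027,201,31419021,abma_ribo,ABMA & RIBO,intervention,0.65,22407317,33403974,1984953,9875,scenario-2 results table year 4
s2,2028,211,33056163,plbo_other,PLBO/Other Tx,comparator_mix,0.20,6611233,35626479,2570316,12182,scenario-2 results table year 5
s2,2028,211,33056163,abma_ribo,ABMA & RIBO,intervention,0.80,29015247,35626479,2570316,12182,scenario-2 results table year 5
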