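# met-hemoglobin whole blood, 145 g Hb/L (1/mm)
# SYNTHETIC approximation; substitute your own table for exact literature curves.
# wavelength_nm	mu_a_per_mm
450	12.4232
452	11.5663
454	10.736
456	9.94193
458	9.19385
460	8.50138
462	7.8742
464	7.32197
466	6.85435
468	6.48101
470	6.21162
472	6.00487
474	5.81344
476	5.63805
478	5.47939
480	5.33814
482	5.21501
484	5.11069
486	5.02587
488	4.96126
490	4.91754
492	4.89059
494	4.87221
496	4.85695
498	4.83937
500	4.81401
502	4.77319
504	4.7164
506	4.64896
508	4.57619
510	4.50343
512	4.4273
514	4.34365
516	4.25667
518	4.1705
520	4.08932
522	4.01287
524	3.93823
526	3.86558
528	3.7951
530	3.72697
532	3.66257
534	3.6016
536	3.54177
538	3.4808
540	3.41639
542	3.34749
544	3.27547
546	3.20166
548	3.12741
550	3.05405
552	2.98069
554	2.90644
556	2.83263
558	2.76061
560	2.6917
562	2.62563
564	2.56132
566	2.499
568	2.43886
570	2.38112
572	2.32428
574	2.268
576	2.21426
578	2.16503
580	2.12231
582	2.08528
584	2.05162
586	2.02093
588	1.99285
590	1.96701
592	1.94035
594	1.91268
596	1.888
598	1.87028
600	1.86349
602	1.86408
604	1.86578
606	1.86846
608	1.87199
610	1.87627
612	1.88116
614	1.88653
616	1.89352
618	1.90835
620	1.92931
622	1.95334
624	1.97737
626	1.99833
628	2.01315
630	2.01878
632	1.99934
634	1.94804
636	1.8754
638	1.79194
640	1.7082
642	1.6117
644	1.49241
646	1.36441
648	1.24184
650	1.1388
652	1.05171
654	0.969322
656	0.894246
658	0.829088
660	0.776453
662	0.732296
664	0.690877
666	0.65226
668	0.616511
670	0.583694
672	0.553875
674	0.527118
676	0.503488
678	0.483051
680	0.465872
682	0.451162
684	0.437956
686	0.426054
688	0.415253
690	0.405354
692	0.396156
694	0.387456
696	0.379055
698	0.370752
700	0.362345
702	0.353979
704	0.345919
706	0.338143
708	0.33063
710	0.323359
712	0.316308
714	0.309455
716	0.30278
718	0.296261
720	0.289876
722	0.283506
724	0.277074
726	0.270622
728	0.264192
730	0.257827
732	0.251569
734	0.245461
736	0.239544
738	0.233861
740	0.228455
742	0.223368
744	0.218642
746	0.214319
748	0.210443
750	0.207054
752	0.20398
754	0.201018
756	0.198162
758	0.19541
760	0.192758
762	0.190203
764	0.187741
766	0.185368
768	0.183082
770	0.180877
772	0.178752
774	0.176702
776	0.174724
778	0.172813
780	0.170968
782	0.169184
784	0.167457
786	0.165784
788	0.164162
790	0.162587
792	0.161055
794	0.159563
796	0.158107
798	0.156684
800	0.155291
802	0.153927
804	0.152598
806	0.151301
808	0.150036
810	0.148803
812	0.1476
814	0.146426
816	0.145281
818	0.144164
820	0.143074
822	0.142011
824	0.140972
826	0.139959
828	0.138969
830	0.138002
832	0.137057
834	0.136133
836	0.13523
838	0.134346
840	0.133481
842	0.132634
844	0.131804
846	0.13099
848	0.130192
850	0.129409
852	0.128637
854	0.127873
856	0.127119
858	0.126375
860	0.12564
862	0.124917
864	0.124205
866	0.123505
868	0.122817
870	0.122141
872	0.121479
874	0.120831
876	0.120197
878	0.119577
880	0.118973
882	0.118385
884	0.117813
886	0.117257
888	0.116719
890	0.116199
892	0.115697
894	0.115213
896	0.114749
898	0.114304
900	0.11388
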